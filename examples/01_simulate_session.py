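"""Simulate a 10-min MEG session with known HFOs and write EDF segments.

Builds the default 275-channel sensor layout, synthesizes a 1/f + power-line
background, injects a handful of ripples and fast ripples with known times
and frequencies, and writes the session as ten 1-min EDF files plus a
ground-truth manifest.
"""

from pathlib import Path

import meghfo as m

out_dir = Path("scratch/example_session")

layout = m.default_layout()
print(f"layout: {len(layout.channel_labels)} channels, "
      f"{len(layout.grouped)} grouped into 11 regions")

# keep the example fast: 8 channels, 2 minutes
small = m.SensorRegionMap(layout.table.iloc[:8].copy())
rec = m.generate_background(small, fs_hz=1200.0, duration_s=120.0, seed=1)

specs = [
    m.InjectionSpec("CL01", onset_s=10.0, peak_freq_hz=200.0, n_cycles=6,
                    amplitude_sd_units=6.0),
    m.InjectionSpec("CL02", onset_s=45.0, peak_freq_hz=267.0, n_cycles=5,
                    amplitude_sd_units=6.0),
    m.InjectionSpec("CL03", onset_s=95.0, peak_freq_hz=120.0, n_cycles=8,
                    amplitude_sd_units=5.0),
]
rec, manifest = m.inject_events(rec, specs)

paths = m.write_edf_segments(rec, out_dir)
manifest.to_json(out_dir / "ground_truth.json")

print(f"wrote {len(paths)} one-minute EDF segments to {out_dir}/")
for spec, true_class in manifest.events:
    print(f"  injected {true_class:12s} {spec.peak_freq_hz:5.0f} Hz on "
          f"{spec.channel_label} at {spec.onset_s:6.2f} s")
# Each line is one ground-truth event; the class follows from the peak
# frequency alone (ripple < 250 Hz <= fast ripple).
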