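# meghfo

Detection and group-level statistics of **high-frequency oscillations
(HFOs)** in multichannel MEG recordings, with a synthetic-cohort simulator
that provides ground truth for every stage of the pipeline.

HFOs — brief oscillatory transients split into **ripples** (80–250 Hz) and
**fast ripples** (250–500 Hz) — are studied as biomarkers of network
hyperexcitability, e.g. in epilepsy and Alzheimer's disease. Detecting them
non-invasively in MEG is hard: events sit barely above a 1/f background
laced with power-line harmonics, and broadband artifacts mimic them across
many sensors at once. `meghfo` implements a complete sensor-level analysis
chain for this problem:

1. **Simulation** (`meghfo.simulate`) — multichannel 1/f background with
   60-Hz harmonics, Hann-tapered oscillatory bursts with amplitude
   calibrated in units of the local 80-Hz-high-passed background SD,
   broadband artifacts, whole cohorts with group/region/hemisphere-specific
   rates, and EDF export (ten 1-min segments per 10-min session).
2. **I/O and preprocessing** (`meghfo.edf`, `meghfo.preprocess`) — plain-EDF
   read/write, session assembly, polyphase downsampling to the common
   1200 Hz analysis rate, zero-phase 80-Hz high-pass, and screening of
   candidate-saturated segments.
3. **Detection** (`meghfo.detect`) — per channel: Tukey-tapered constant-Q
   Morlet time-frequency transform (12 voices/octave over 3 octaves from
   80 Hz), robust per-band normalization (IQR outlier exclusion, normal
   fit, z-scoring), strict 8-neighbour local-maximum search at threshold
   score 20, event assembly with a 1.4-cycle minimum duration and a
   10-division frequency-spread cap, and ripple/fast-ripple classification
   by peak frequency.
4. **Artifact rejection** (`meghfo.filters`) — the two-stage filter: at most
   5 candidates per 400 ms across all channels (larger clusters collapse to
   the highest-power event), then removal of candidates whose peak
   high-passed amplitude is below 3× the SD of their 400-ms window.
5. **Statistics** (`meghfo.stats`) — per-channel/per-class rate tables,
   channel-wise regional group comparisons with normality-gated test
   selection (t / ANOVA+Tukey vs Mann-Whitney / Kruskal-Wallis+Dunn),
   cross-region Spearman summaries, drug-vs-placebo contrasts, and the
   hemispheric asymmetry index

   ```
   AI = 200 · (rate_left − rate_right) / (rate_left + rate_right) ∈ [−200, 200]
   ```

   with one-sample (vs 0) and between-group tests.

## Worked example

```python
import meghfo as m

layout = m.SensorRegionMap(m.default_layout().table.iloc[:4].copy())
rec = m.generate_background(layout, fs_hz=1200.0, duration_s=60.0, seed=2)
rec, truth = m.inject_events(rec, [
    m.InjectionSpec("CL01", 10.0, 140.0, n_cycles=6, amplitude_sd_units=6.0),
    m.InjectionSpec("CL02", 25.0, 300.0, n_cycles=5, amplitude_sd_units=6.0),
    m.InjectionSpec("CL03", 40.0, 190.0, n_cycles=6, amplitude_sd_units=2.0),
])
events = m.detect_recording(rec)
kept, audits = m.apply_filters(events, rec)
```

Running this (it is `examples/02_detect_and_filter.py`) prints:

```
detector: 3 candidates
  CL01   10.02 s  151.0 Hz  score  441.5  ripple
  CL02   25.01 s  302.0 Hz  score   47.7  fast_ripple
  CL03   40.01 s  201.6 Hz  score   20.8  ripple
after artifact filters: 2 kept, 1 rejected
```

The two 6-SD injections are recovered with the right class (peak-frequency
estimates carry the quantization of the 12-voice log grid); the weak 2-SD
injection scrapes past the detection threshold but falls to the
amplitude-ratio filter, exactly the event type that stage exists to remove.
The other scripts in `examples/` walk through session simulation with EDF
export and the full cohort-level statistics (regional comparisons, Spearman
summary, asymmetry index).

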