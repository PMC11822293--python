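"""Synthetic MEG cohorts with ground-truth injected HFOs.

Every downstream stage — detection, artifact filtering, rates, statistics —
is exercised against recordings whose event content is known exactly.  The
background model is the simplest one that reproduces the salient noise
features of resting-state MEG: per-channel 1/f ("pink") noise plus strong
power-line harmonics at multiples of 60 Hz.  Oscillatory events are tapered
sinusoidal bursts whose amplitude is calibrated in units of the local SD of
the 80-Hz high-passed background, so detector and ratio-filter operating
points can be probed directly.  Occasional broadband transients spanning
most channels emulate the artifacts the density filter and segment screening
are designed to remove.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal as _sig

from .core import Recording
from .detect import RIPPLE_FR_BOUNDARY_HZ, classify_band
from .layout import REGION_DEF, SensorRegionMap, default_layout
from .preprocess import _filtfilt_compensated, _highpass_taps

__all__ = [
    "InjectionSpec", "GroundTruthManifest", "GroupSpec", "CohortSpec",
    "CohortSubject", "generate_background", "inject_events",
    "inject_broadband_artifacts", "make_cohort", "write_edf_segments",
    "default_layout",
]

#: guard band kept free of events at each segment edge, seconds
EDGE_GUARD_S = 1.0

DEFAULT_AMPLITUDE_SD = 6.0
DEFAULT_CYCLE_RANGE = (4, 8)


@dataclass(frozen=True)
class InjectionSpec:
    """One oscillatory burst to add to a recording.

    ``amplitude_sd_units`` scales the burst's peak amplitude in multiples of
    the SD of the channel's 80-Hz high-passed background over the 400 ms
    around the event.  Duration is ``n_cycles / peak_freq_hz`` seconds, with
    a Hann taper over the full burst.
    """

    channel_label: str
    onset_s: float
    peak_freq_hz: float
    n_cycles: float
    amplitude_sd_units: float
    taper: str = "hann"

    def __post_init__(self) -> None:
        if not 80.0 <= self.peak_freq_hz <= 500.0:
            raise ValueError("peak_freq_hz must lie in [80, 500] Hz")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.taper != "hann":
            raise ValueError(f"unsupported taper {self.taper!r}")

    @property
    def duration_s(self) -> float:
        return self.n_cycles / self.peak_freq_hz

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class GroundTruthManifest:
    """Injected-event records: the oracle for detection performance."""

    events: list[tuple[InjectionSpec, str]]
    seed: int = 0
    background_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for spec, true_class in self.events:
            if true_class != classify_band(spec.peak_freq_hz):
                raise ValueError(
                    f"true_class {true_class!r} inconsistent with "
                    f"{spec.peak_freq_hz} Hz"
                )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "background_params": self.background_params,
            "events": [
                {**asdict(spec), "true_class": true_class}
                for spec, true_class in self.events
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        payload = json.loads(Path(path).read_text())
        events = []
        for rec in payload["events"]:
            true_class = rec.pop("true_class")
            events.append((InjectionSpec(**rec), true_class))
        return cls(
            events=events,
            seed=payload["seed"],
            background_params=payload["background_params"],
        )


def generate_background(
    layout: SensorRegionMap,
    fs_hz: float,
    duration_s: float,
    pink_exponent: float = 1.0,
    line_hz: float = 60.0,
    line_harmonics: int = 8,
    line_amplitude: float = 0.5,
    seed: int = 0,
) -> Recording:
    """Multichannel 1/f noise plus power-line harmonics.

    Each channel is independent spectrally shaped Gaussian noise
    (power ~ 1/f^pink_exponent, unit SD) plus sinusoids at
    ``line_hz, 2*line_hz, ..., line_harmonics*line_hz`` of peak amplitude
    ``line_amplitude`` with random phases.  Identical seeds give
    bit-identical output.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if line_amplitude > 0 and fs_hz < 2.0 * line_hz * line_harmonics:
        raise ValueError(
            f"sampling rate {fs_hz} Hz violates Nyquist for "
            f"{line_harmonics} harmonics of {line_hz} Hz"
        )
    rng = np.random.default_rng(seed)
    labels = layout.channel_labels
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    shaping = np.ones_like(freqs)
    if pink_exponent != 0:
        shaping[1:] = freqs[1:] ** (-pink_exponent / 2.0)
        shaping[0] = 0.0
    white = rng.standard_normal((len(labels), n))
    samples = np.fft.irfft(np.fft.rfft(white, axis=1) * shaping, n, axis=1)
    sd = samples.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    samples /= sd
    if line_amplitude > 0:
        phases = rng.uniform(0, 2 * np.pi, (len(labels), line_harmonics))
        for h in range(1, line_harmonics + 1):
            samples += line_amplitude * np.sin(
                2 * np.pi * h * line_hz * t[None, :] + phases[:, [h - 1]]
            )
    return Recording(samples=samples, fs_hz=fs_hz, channel_labels=list(labels))


def _local_hp_sd(
    hp_channel: np.ndarray, fs: float, spec: InjectionSpec, window_s: float = 0.4
) -> float:
    centre = spec.onset_s + spec.duration_s / 2.0
    half = int(round(window_s / 2.0 * fs))
    c = int(round(centre * fs))
    lo = max(0, c - half)
    hi = min(hp_channel.size, c + half)
    return float(np.std(hp_channel[lo:hi]))


def inject_events(
    rec: Recording, specs: list[InjectionSpec]
) -> tuple[Recording, GroundTruthManifest]:
    """Add tapered sinusoidal bursts to a recording.

    Each burst is a Hann-tapered sinusoid of ``n_cycles`` cycles at
    ``peak_freq_hz``, scaled so its peak amplitude equals
    ``amplitude_sd_units`` times the SD of the channel's 80-Hz high-passed
    *background* (pre-injection) over the surrounding 400 ms.  Samples
    outside the injected windows are untouched.  Overlapping bursts on one
    channel are rejected.
    """
    out = rec.copy()
    by_channel: dict[str, list[InjectionSpec]] = {}
    for spec in specs:
        if spec.channel_label not in rec.channel_labels:
            raise KeyError(f"unknown channel {spec.channel_label!r}")
        if spec.onset_s < 0 or spec.offset_s > rec.duration_s:
            raise ValueError(
                f"event at {spec.onset_s:.3f}s on {spec.channel_label} "
                f"outside the recording"
            )
        by_channel.setdefault(spec.channel_label, []).append(spec)

    fs = rec.fs_hz
    taps = _sig.firwin(_highpass_taps(fs, 80.0), 80.0, pass_zero=False, fs=fs)
    events: list[tuple[InjectionSpec, str]] = []
    for label, chan_specs in by_channel.items():
        chan_specs.sort(key=lambda s: s.onset_s)
        for a, b in zip(chan_specs, chan_specs[1:]):
            if b.onset_s < a.offset_s:
                raise ValueError(
                    f"overlapping injections on {label} at "
                    f"{a.onset_s:.3f}s and {b.onset_s:.3f}s"
                )
        idx = rec.channel_index(label)
        hp = _filtfilt_compensated(taps, rec.samples[idx][None, :])[0]
        for spec in chan_specs:
            sd = _local_hp_sd(hp, fs, spec)
            i0 = int(round(spec.onset_s * fs))
            n_burst = max(2, int(round(spec.duration_s * fs)))
            tt = np.arange(n_burst) / fs
            burst = (
                spec.amplitude_sd_units
                * sd
                * np.sin(2 * np.pi * spec.peak_freq_hz * tt)
                * np.hanning(n_burst)
            )
            out.samples[idx, i0: i0 + n_burst] += burst
    for spec in sorted(specs, key=lambda s: (s.onset_s, s.channel_label)):
        events.append((spec, classify_band(spec.peak_freq_hz)))
    return out, GroundTruthManifest(events=events)


def inject_broadband_artifacts(
    rec: Recording,
    n_artifacts: int,
    seed: int = 0,
    duration_s: float = 0.05,
    amplitude_sd_units: float = 8.0,
    channel_fraction: float = 0.8,
) -> Recording:
    """Add brief broadband transients hitting most channels simultaneously.

    Emulates the movement/electronic artifacts that the density filter and
    segment screening are designed to reject: at each artifact time a
    Hann-tapered white-noise burst is added to a random ``channel_fraction``
    of channels, scaled per channel to ``amplitude_sd_units`` x its SD.
    """
    rng = np.random.default_rng(seed)
    out = rec.copy()
    n_burst = max(2, int(round(duration_s * rec.fs_hz)))
    taper = np.hanning(n_burst)
    lo = EDGE_GUARD_S
    hi = rec.duration_s - EDGE_GUARD_S - duration_s
    if hi <= lo:
        raise ValueError("recording too short for artifact placement")
    for _ in range(n_artifacts):
        t0 = rng.uniform(lo, hi)
        i0 = int(round(t0 * rec.fs_hz))
        picks = rng.random(rec.n_channels) < channel_fraction
        for idx in np.nonzero(picks)[0]:
            sd = float(np.std(rec.samples[idx]))
            out.samples[idx, i0: i0 + n_burst] += (
                amplitude_sd_units * sd * rng.standard_normal(n_burst) * taper
            )
    return out


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group.

    ``regional_rate_profile`` maps region code -> {class -> events per
    10 minutes}.  ``hemisphere_asymmetry`` multiplies the left-hemisphere
    regional rates (right and midline unchanged); 1.0 means symmetric.
    """

    group_name: str
    n_subjects: int
    regional_rate_profile: dict[str, dict[str, float]]
    hemisphere_asymmetry: float | None = None

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        for region, per_class in self.regional_rate_profile.items():
            if region not in REGION_DEF:
                raise ValueError(f"unknown region {region!r}")
            for cls, rate in per_class.items():
                if cls not in ("ripple", "fast_ripple"):
                    raise ValueError(f"unknown class {cls!r}")
                if rate < 0:
                    raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    fs_hz: float = 1200.0
    duration_s: float = 600.0
    seed: int = 0
    amplitude_sd_units: float = DEFAULT_AMPLITUDE_SD
    cycle_range: tuple[int, int] = DEFAULT_CYCLE_RANGE
    artifacts_per_subject: int = 0
    background: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort needs at least one group")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


#: class -> frequency band for uniform event-frequency sampling
CLASS_BANDS = {
    "ripple": (80.0, RIPPLE_FR_BOUNDARY_HZ),
    "fast_ripple": (RIPPLE_FR_BOUNDARY_HZ, 500.0),
}


@dataclass
class CohortSubject:
    subject_id: str
    group_name: str
    recording: Recording
    manifest: GroundTruthManifest


def make_cohort(
    spec: CohortSpec,
    layout: SensorRegionMap | None = None,
    synthesize_signal: bool = True,
) -> list[CohortSubject]:
    """Simulate a cohort of subjects with group/region-specific HFO rates.

    Per subject and region, event counts per class are Poisson with mean
    ``profile_rate * duration_s / 600``; events land on uniformly chosen
    channels of the region at uniform times (1-s guard from the edges) and
    uniform frequencies within the class band.  Fully seed-reproducible.

    With ``synthesize_signal=False`` only the ground-truth manifests are
    drawn (``recording`` is None) — the fast path for purely rate-level
    studies; the event draw is identical either way.
    """
    layout = layout if layout is not None else default_layout()
    root = np.random.SeedSequence(spec.seed)
    out: list[CohortSubject] = []
    for gi, group in enumerate(spec.groups):
        group_seq = root.spawn(len(spec.groups))[gi]
        subject_seqs = group_seq.spawn(group.n_subjects)
        for si in range(group.n_subjects):
            subject_id = f"{group.group_name}-{si + 1:03d}"
            out.append(
                _make_subject(
                    subject_id, group, spec, layout, subject_seqs[si],
                    synthesize_signal,
                )
            )
    return out


def _make_subject(
    subject_id: str,
    group: GroupSpec,
    spec: CohortSpec,
    layout: SensorRegionMap,
    seq: np.random.SeedSequence,
    synthesize_signal: bool = True,
) -> CohortSubject:
    bg_seed, ev_seed, art_seed = (int(s.generate_state(1)[0] % (2 ** 31))
                                  for s in seq.spawn(3))
    rng = np.random.default_rng(ev_seed)
    specs: list[InjectionSpec] = []
    occupied: dict[str, list[tuple[float, float]]] = {}
    t_lo = EDGE_GUARD_S
    t_hi = spec.duration_s - EDGE_GUARD_S
    for region, per_class in group.regional_rate_profile.items():
        channels = layout.channels_in_region(region)
        hemi = REGION_DEF[region][0]
        mult = (
            group.hemisphere_asymmetry
            if group.hemisphere_asymmetry is not None and hemi == "left"
            else 1.0
        )
        for cls, rate in per_class.items():
            lam = rate * mult * spec.duration_s / 600.0
            count = rng.poisson(lam)
            f_lo, f_hi = CLASS_BANDS[cls]
            for _ in range(count):
                freq = rng.uniform(f_lo, min(f_hi, 500.0))
                n_cycles = int(rng.integers(spec.cycle_range[0],
                                            spec.cycle_range[1] + 1))
                dur = n_cycles / freq
                for _attempt in range(1000):
                    chan = channels[rng.integers(len(channels))]
                    onset = rng.uniform(t_lo, t_hi - dur)
                    spans = occupied.setdefault(chan, [])
                    if all(onset + dur <= a or onset >= b for a, b in spans):
                        spans.append((onset, onset + dur))
                        specs.append(
                            InjectionSpec(
                                channel_label=chan,
                                onset_s=onset,
                                peak_freq_hz=freq,
                                n_cycles=n_cycles,
                                amplitude_sd_units=spec.amplitude_sd_units,
                            )
                        )
                        break
                else:  # pragma: no cover - unreachable at realistic rates
                    raise RuntimeError("could not place event without overlap")
    if synthesize_signal:
        rec = generate_background(
            layout, spec.fs_hz, spec.duration_s, seed=bg_seed,
            **spec.background,
        )
        rec, manifest = inject_events(rec, specs)
        if spec.artifacts_per_subject:
            rec = inject_broadband_artifacts(
                rec, spec.artifacts_per_subject, seed=art_seed
            )
    else:
        rec = None
        manifest = GroundTruthManifest(
            events=[
                (s, classify_band(s.peak_freq_hz))
                for s in sorted(specs, key=lambda s: (s.onset_s, s.channel_label))
            ]
        )
    manifest.seed = int(seq.generate_state(1)[0] % (2 ** 31))
    manifest.background_params = dict(spec.background)
    return CohortSubject(
        subject_id=subject_id,
        group_name=group.group_name,
        recording=rec,
        manifest=manifest,
    )


def write_edf_segments(
    rec: Recording, out_dir: str | Path, segment_s: float = 60.0,
    pad: bool = False,
) -> list[Path]:
    """Split a recording into fixed-length EDF segment files.

    A 600-s session yields ten 1-min files.  The duration must be a multiple
    of ``segment_s`` unless ``pad`` is set, in which case the tail is
    zero-padded to a full segment.
    """
    from .edf import write_edf

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_seg_f = rec.duration_s / segment_s
    n_seg = int(np.ceil(n_seg_f - 1e-9))
    if abs(n_seg_f - round(n_seg_f)) > 1e-9:
        if not pad:
            raise ValueError(
                f"duration {rec.duration_s}s is not a multiple of {segment_s}s"
            )
        total = int(round(n_seg * segment_s * rec.fs_hz))
        padded = np.zeros((rec.n_channels, total))
        padded[:, : rec.n_samples] = rec.samples
        rec = Recording(padded, rec.fs_hz, list(rec.channel_labels),
                        rec.start_time_s)
    spseg = int(round(segment_s * rec.fs_hz))
    paths = []
    for k in range(n_seg):
        seg = Recording(
            samples=rec.samples[:, k * spseg: (k + 1) * spseg],
            fs_hz=rec.fs_hz,
            channel_labels=list(rec.channel_labels),
            start_time_s=rec.start_time_s + k * segment_s,
        )
        path = out_dir / f"segment_{k:03d}.edf"
        write_edf(seg, path)
        paths.append(path)
    return paths
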