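"""Core containers shared by every stage of the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np


@dataclass
class Recording:
    """A multichannel electrophysiology recording.

    Samples are stored channel-major (``n_channels x n_samples``) in arbitrary
    field units (the simulator labels them femtotesla, but nothing downstream
    depends on the physical unit).  ``start_time_s`` is the session-relative
    onset of the first sample; event times produced by the detector are
    session-relative seconds, 0-based, with half-open intervals
    ``[onset, offset)``.
    """

    samples: np.ndarray
    fs_hz: float
    channel_labels: list[str]
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channel x time array")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel {label!r}") from None

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.channel_index(label)]

    def copy(self) -> "Recording":
        return replace(
            self,
            samples=self.samples.copy(),
            channel_labels=list(self.channel_labels),
        )


@dataclass
class SessionBundle:
    """An ordered list of contiguous segments from one recording session."""

    segments: list[Recording]
    subject_id: str = ""
    visit_id: str = ""

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("session must contain at least one segment")
        first = self.segments[0]
        t = first.start_time_s
        for seg in self.segments:
            if seg.channel_labels != first.channel_labels:
                raise ValueError("segments must share channel labels")
            if seg.fs_hz != first.fs_hz:
                raise ValueError("segments must share the sampling rate")
            if not np.isclose(seg.start_time_s, t, atol=0.5 / first.fs_hz):
                raise ValueError("segments must be contiguous in time")
            t = seg.start_time_s + seg.duration_s

    def concatenate(self) -> Recording:
        first = self.segments[0]
        return Recording(
            samples=np.concatenate([s.samples for s in self.segments], axis=1),
            fs_hz=first.fs_hz,
            channel_labels=list(first.channel_labels),
            start_time_s=first.start_time_s,
        )


@dataclass(frozen=True)
class CandidateEvent:
    """One detected oscillatory event on a single channel.

    ``score`` is the normalized (z-like) time-frequency energy at the event's
    local maximum; ``power`` is the raw pre-normalization energy there.
    ``duration_cycles`` is the event duration expressed in oscillation periods
    at the peak frequency.
    """

    channel_label: str
    onset_s: float
    offset_s: float
    peak_time_s: float
    peak_freq_hz: float
    score: float
    power: float
    class_label: str
    duration_cycles: float

    def __post_init__(self) -> None:
        if not self.onset_s < self.offset_s:
            raise ValueError("event onset must precede offset")
        if self.class_label not in ("ripple", "fast_ripple"):
            raise ValueError(f"unknown class label {self.class_label!r}")


def events_to_frame(events: Sequence[CandidateEvent]):
    """Tabulate events as a pandas DataFrame (one row per event)."""
    import pandas as pd

    cols = [
        "channel_label", "onset_s", "offset_s", "peak_time_s",
        "peak_freq_hz", "score", "power", "class_label", "duration_cycles",
    ]
    return pd.DataFrame(
        [{c: getattr(e, c) for c in cols} for e in events], columns=cols
    )
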