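"""Two-stage artifact rejection of detector candidates.

Stage 1 (density): transient artifacts hit many sensors at once, so bursts of
more than five candidates within 400 ms across all channels are collapsed to
the single highest-power candidate.  Stage 2 (amplitude ratio): the recording
is high-pass filtered at 80 Hz, per-channel standard deviations are taken
over consecutive 400-ms windows, and candidates whose peak high-frequency
amplitude is less than 3x the SD of their window are dropped as
low-amplitude noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CandidateEvent, Recording
from .preprocess import highpass


@dataclass(frozen=True)
class FilterConfig:
    """Artifact-filter settings (defaults are the standard operating point)."""

    density_window_s: float = 0.4
    density_max_count: int = 5
    ratio_threshold: float = 3.0
    ratio_highpass_hz: float = 80.0
    sd_window_s: float = 0.4
    #: "collapse": an overfull cluster keeps only its highest-power event;
    #: "top_n": it keeps its density_max_count highest-power events.
    overfull_policy: str = "collapse"
    #: "linkage": clusters chain events whose successive gaps are within the
    #: window; "tumbling": fixed consecutive windows partition the time axis.
    clustering: str = "linkage"

    def __post_init__(self) -> None:
        if min(
            self.density_window_s, self.density_max_count,
            self.ratio_threshold, self.ratio_highpass_hz, self.sd_window_s,
        ) <= 0:
            raise ValueError("all filter parameters must be positive")
        if self.overfull_policy not in ("collapse", "top_n"):
            raise ValueError(f"unknown overfull_policy {self.overfull_policy!r}")
        if self.clustering not in ("linkage", "tumbling"):
            raise ValueError(f"unknown clustering {self.clustering!r}")


@dataclass(frozen=True)
class FilterAudit:
    candidate_id: str
    stage: str                 # "density" | "ratio"
    kept: bool
    ratio_value: float | None = None
    cluster_size: int | None = None


def _candidate_id(e: CandidateEvent) -> str:
    return f"{e.channel_label}@{e.peak_time_s:.6f}"


def _power_key(e: CandidateEvent) -> tuple:
    # highest power wins; ties broken by earlier peak, then channel label
    return (-e.power, e.peak_time_s, e.channel_label)


def density_filter(
    events: Sequence[CandidateEvent], cfg: FilterConfig = FilterConfig()
) -> tuple[list[CandidateEvent], list[FilterAudit]]:
    """Collapse cross-channel candidate bursts.

    Events are clustered by peak time across all channels (single-linkage by
    default: a gap larger than the window starts a new cluster).  Clusters of
    at most ``density_max_count`` events pass intact; larger clusters —
    the signature of a broadband artifact — are reduced per
    ``overfull_policy``.
    """
    events = sorted(events, key=lambda e: (e.peak_time_s, e.channel_label))
    clusters: list[list[CandidateEvent]] = []
    if cfg.clustering == "linkage":
        for e in events:
            if (
                clusters
                and e.peak_time_s - clusters[-1][-1].peak_time_s
                <= cfg.density_window_s
            ):
                clusters[-1].append(e)
            else:
                clusters.append([e])
    else:  # tumbling windows anchored at t=0
        bins: dict[int, list[CandidateEvent]] = {}
        for e in events:
            bins.setdefault(int(e.peak_time_s // cfg.density_window_s), []).append(e)
        clusters = [bins[k] for k in sorted(bins)]

    kept: list[CandidateEvent] = []
    audits: list[FilterAudit] = []
    for cluster in clusters:
        if len(cluster) <= cfg.density_max_count:
            survivors = set(map(id, cluster))
        elif cfg.overfull_policy == "collapse":
            survivors = {id(min(cluster, key=_power_key))}
        else:
            top = sorted(cluster, key=_power_key)[: cfg.density_max_count]
            survivors = set(map(id, top))
        for e in cluster:
            ok = id(e) in survivors
            audits.append(
                FilterAudit(
                    candidate_id=_candidate_id(e),
                    stage="density",
                    kept=ok,
                    cluster_size=len(cluster),
                )
            )
            if ok:
                kept.append(e)
    kept.sort(key=lambda e: (e.peak_time_s, e.channel_label))
    return kept, audits


def amplitude_ratio_filter(
    events: Sequence[CandidateEvent],
    rec: Recording,
    cfg: FilterConfig = FilterConfig(),
) -> tuple[list[CandidateEvent], list[FilterAudit]]:
    """Drop candidates with weak high-frequency amplitude.

    The recording is high-pass filtered at ``ratio_highpass_hz``; per channel
    the SD of the filtered amplitude is computed over consecutive
    (non-overlapping) ``sd_window_s`` windows.  Each candidate's ratio is its
    maximum absolute filtered amplitude within the event span divided by the
    SD of the window containing its peak; ratios below ``ratio_threshold``
    are rejected.
    """
    if not events:
        return [], []
    hp = highpass(rec, cfg.ratio_highpass_hz)
    fs = hp.fs_hz
    win = int(round(cfg.sd_window_s * fs))
    kept: list[CandidateEvent] = []
    audits: list[FilterAudit] = []
    for e in sorted(events, key=lambda ev: (ev.peak_time_s, ev.channel_label)):
        sig = hp.channel(e.channel_label)
        i0 = int(round((e.onset_s - rec.start_time_s) * fs))
        i1 = int(round((e.offset_s - rec.start_time_s) * fs))
        ip = int((e.peak_time_s - rec.start_time_s) * fs)
        if i0 < 0 or i1 > sig.size or not 0 <= ip < sig.size:
            raise ValueError(
                f"event {_candidate_id(e)} lies outside the recording span"
            )
        w0 = (ip // win) * win
        sd = float(np.std(sig[w0: w0 + win]))
        peak_amp = float(np.max(np.abs(sig[i0:i1]))) if i1 > i0 else 0.0
        ratio = peak_amp / sd if sd > 0 else np.inf
        ok = ratio >= cfg.ratio_threshold
        audits.append(
            FilterAudit(
                candidate_id=_candidate_id(e),
                stage="ratio",
                kept=ok,
                ratio_value=ratio,
            )
        )
        if ok:
            kept.append(e)
    return kept, audits


def apply_filters(
    events: Sequence[CandidateEvent],
    rec: Recording,
    cfg: FilterConfig = FilterConfig(),
) -> tuple[list[CandidateEvent], list[FilterAudit]]:
    """Density filter, then amplitude-ratio filter; audits from both stages."""
    dense_kept, audits = density_filter(events, cfg)
    ratio_kept, ratio_audits = amplitude_ratio_filter(dense_kept, rec, cfg)
    return ratio_kept, audits + ratio_audits


def audits_to_frame(audits: Sequence[FilterAudit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "candidate_id": a.candidate_id,
                "stage": a.stage,
                "kept": a.kept,
                "ratio_value": a.ratio_value,
                "cluster_size": a.cluster_size,
            }
            for a in audits
        ]
    )
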