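"""Plain EDF (European Data Format) reading and writing.

Implements the classic 16-bit EDF layout: a 256-byte fixed header, 256 bytes
of per-signal header fields, then data records of little-endian int16 samples.
The dialect written here is deliberately narrow — plain EDF (not EDF+), one
data record per second, every signal at the same sampling rate — which is all
the pipeline needs for 1-min MEG segments.  The reader accepts any plain EDF
file with uniform per-signal rates.

Physical scaling uses a symmetric range per channel so that a write/read
round trip reproduces samples to within one 16-bit quantization step.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .core import Recording

_DIG_MAX = 32767
_DIG_MIN = -32767


def _fit_ascii_float(value: float, width: int = 8) -> str:
    """Render a float into EDF's fixed-width ASCII field, value-preserving.

    Returns a string of at most ``width`` chars whose float() round trip is
    >= ``value`` (so the physical range never undershoots the data).
    """
    for digits in range(7, 0, -1):
        s = f"{value:.{digits}G}"
        if len(s) <= width and float(s) >= value:
            return s
    # last resort: round up at 1 significant digit
    s = f"{value * 1.05:.1G}"
    return s[:width]


def _pad(s: str, width: int) -> bytes:
    b = s.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field {s!r} exceeds {width} ascii chars")
    return b.ljust(width)


def write_edf(
    rec: Recording,
    path: str | Path,
    physical_dimension: str = "fT",
) -> Path:
    """Write a Recording as one plain EDF file with 1-s data records.

    The recording duration must be an integral number of seconds and the
    sampling rate an integer.
    """
    path = Path(path)
    fs = rec.fs_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_records = rec.n_samples / fs
    if abs(n_records - round(n_records)) > 1e-9:
        raise ValueError("recording length must be a whole number of seconds")
    n_records = int(round(n_records))
    ns = rec.n_channels

    # symmetric physical range per channel, ascii-representable
    pmax_strs = []
    scales = np.empty(ns)
    for i in range(ns):
        amax = float(np.max(np.abs(rec.samples[i])))
        if amax == 0 or not math.isfinite(amax):
            amax = 1.0
        s = _fit_ascii_float(amax, width=7)  # leave room for the minus sign
        pmax_strs.append(s)
        scales[i] = float(s) / _DIG_MAX

    start_s = int(round(rec.start_time_s)) % 86400
    hh, rem = divmod(start_s, 3600)
    mm, ss = divmod(rem, 60)

    header = bytearray()
    header += _pad("0", 8)                      # version
    header += _pad("X X X X", 80)               # patient id (anonymous)
    header += _pad("Startdate 01-JAN-2000 synthetic", 80)
    header += _pad("01.01.00", 8)               # start date
    header += _pad(f"{hh:02d}.{mm:02d}.{ss:02d}", 8)
    header += _pad(str(256 * (1 + ns)), 8)      # header byte count
    header += _pad("", 44)                      # reserved (plain EDF)
    header += _pad(str(n_records), 8)
    header += _pad("1", 8)                      # record duration, seconds
    header += _pad(str(ns), 4)

    def field(values: list[str], width: int) -> bytes:
        return b"".join(_pad(v, width) for v in values)

    labels = [lab[:16] for lab in rec.channel_labels]
    header += field(labels, 16)
    header += field([""] * ns, 80)              # transducer
    header += field([physical_dimension] * ns, 8)
    header += field(["-" + s for s in pmax_strs], 8)   # physical min
    header += field(pmax_strs, 8)                      # physical max
    header += field([str(_DIG_MIN)] * ns, 8)
    header += field([str(_DIG_MAX)] * ns, 8)
    header += field([""] * ns, 80)              # prefiltering
    header += field([str(fs)] * ns, 8)          # samples per record
    header += field([""] * ns, 32)              # reserved

    digital = np.empty((ns, rec.n_samples), dtype="<i2")
    for i in range(ns):
        d = np.round(rec.samples[i] / scales[i])
        digital[i] = np.clip(d, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_records):
            sl = slice(r * fs, (r + 1) * fs)
            fh.write(digital[:, sl].tobytes())  # channel-sequential per record
    return path


def read_edf(path: str | Path) -> Recording:
    """Read a plain EDF file into a Recording (physical units).

    Raises ValueError for malformed or truncated files and for files whose
    signals do not share a single sampling rate.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise ValueError(f"{path}: not an EDF file (header truncated)")

    def ascii_field(off: int, width: int) -> str:
        return raw[off:off + width].decode("ascii", errors="replace").strip()

    try:
        header_bytes = int(ascii_field(184, 8))
        n_records = int(ascii_field(236, 8))
        record_dur = float(ascii_field(244, 8))
        ns = int(ascii_field(252, 4))
    except ValueError as exc:
        raise ValueError(f"{path}: malformed EDF header ({exc})") from None
    if ns <= 0 or header_bytes != 256 * (1 + ns):
        raise ValueError(f"{path}: inconsistent EDF header")
    if len(raw) < header_bytes:
        raise ValueError(f"{path}: truncated EDF header")

    def sig_fields(block_off: int, width: int) -> list[str]:
        base = 256 + block_off
        return [
            raw[base + i * width: base + (i + 1) * width]
            .decode("ascii", errors="replace").strip()
            for i in range(ns)
        ]

    # per-signal header blocks, in EDF order
    off = 0
    labels = sig_fields(off, 16); off += 16 * ns
    off += 80 * ns                                   # transducer
    off += 8 * ns                                    # physical dimension
    phys_min = [float(v) for v in sig_fields(off, 8)]; off += 8 * ns
    phys_max = [float(v) for v in sig_fields(off, 8)]; off += 8 * ns
    dig_min = [int(v) for v in sig_fields(off, 8)]; off += 8 * ns
    dig_max = [int(v) for v in sig_fields(off, 8)]; off += 8 * ns
    off += 80 * ns                                   # prefiltering
    nsamp = [int(v) for v in sig_fields(off, 8)]

    if len(set(nsamp)) != 1:
        raise ValueError(f"{path}: mixed per-signal sampling rates unsupported")
    spr = nsamp[0]
    fs = spr / record_dur

    record_bytes = 2 * spr * ns
    if n_records < 0:  # unknown count: infer from file size
        n_records, rem = divmod(len(raw) - header_bytes, record_bytes)
        if rem:
            raise ValueError(f"{path}: truncated data record")
    expected = header_bytes + n_records * record_bytes
    if len(raw) < expected:
        raise ValueError(
            f"{path}: truncated EDF data "
            f"({len(raw)} bytes, expected {expected})"
        )

    data = np.frombuffer(
        raw, dtype="<i2", count=n_records * spr * ns, offset=header_bytes
    ).reshape(n_records, ns, spr)
    samples = np.empty((ns, n_records * spr))
    for i in range(ns):
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        samples[i] = (
            (data[:, i, :].reshape(-1).astype(np.float64) - dig_min[i]) * gain
            + phys_min[i]
        )

    start = ascii_field(176, 8)
    try:
        hh, mm, ss = (int(p) for p in start.split("."))
        start_time_s = float(hh * 3600 + mm * 60 + ss)
    except ValueError:
        start_time_s = 0.0

    return Recording(
        samples=samples,
        fs_hz=fs,
        channel_labels=labels,
        start_time_s=start_time_s,
    )
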