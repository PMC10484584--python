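"""Waveform container and I/O (CSV dialect and 16-bit continuous EDF).

The CSV dialect is ``label,rate_hz,start_s`` on the first line followed by one
sample per line. EDF support covers the plain continuous flavour used for
polygraphy exports: 16-bit samples, one set of signals, fixed-length data
records. Physical scaling is chosen per channel from the data range, so a
write/read round trip reproduces samples to within one half quantization step
of the 16-bit encoding.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class WaveformError(ValueError):
    pass


@dataclass
class Waveform:
    """A uniformly sampled signal channel.

    Parameters
    ----------
    label : channel name (e.g. ``"PPG"``, ``"Flow"``).
    rate : sampling frequency in Hz, > 0.
    samples : 1-D float array.
    start : offset of the first sample in seconds from recording start.
    """

    label: str
    rate: float
    samples: np.ndarray
    start: float = 0.0

    def __post_init__(self) -> None:
        if not (self.rate > 0 and math.isfinite(self.rate)):
            raise WaveformError(f"rate must be > 0, got {self.rate}")
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise WaveformError("samples must be one-dimensional")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise WaveformError(f"non-finite samples in channel {self.label!r}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.start + np.arange(self.samples.size) / self.rate


# ---------------------------------------------------------------------------
# CSV dialect

def write_waveform_csv(w: Waveform, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{w.label},{float(w.rate)!r},{float(w.start)!r}\n")
        for x in w.samples:
            fh.write(f"{float(x)!r}\n")


def read_waveform_csv(path: str | Path) -> Waveform:
    with open(path) as fh:
        header = fh.readline().strip()
        parts = header.split(",")
        if len(parts) != 3:
            raise WaveformError(f"bad CSV waveform header: {header!r}")
        label, rate, start = parts[0], float(parts[1]), float(parts[2])
        if rate <= 0:
            raise WaveformError(f"rate must be > 0, got {rate}")
        samples = np.array([float(line) for line in fh if line.strip()])
    return Waveform(label=label, rate=rate, samples=samples, start=start)


# ---------------------------------------------------------------------------
# EDF (continuous, 16-bit)

_EDF_HDR = 256  # bytes, plus 256 per signal


def _ascii(value: str, width: int) -> bytes:
    s = value[:width].ljust(width)
    return s.encode("ascii")


def write_edf(waveforms: list[Waveform], path: str | Path, *, record_duration: float = 1.0,
              patient: str = "X", recording: str = "X") -> None:
    """Write channels to a plain EDF file.

    All channels must start at 0 and have ``rate * record_duration`` integral.
    Channels are zero-padded to the longest channel's duration.
    """
    if not waveforms:
        raise WaveformError("no channels to write")
    for w in waveforms:
        if w.start != 0:
            raise WaveformError("EDF export requires all channels to start at 0 s")
        spr = w.rate * record_duration
        if abs(spr - round(spr)) > 1e-9 or round(spr) < 1:
            raise WaveformError(
                f"rate {w.rate} Hz incompatible with record duration {record_duration}s"
            )
    total = max(w.duration for w in waveforms)
    n_records = int(math.ceil(total / record_duration - 1e-9))
    ns = len(waveforms)

    phys_min, phys_max, scaled = [], [], []
    for w in waveforms:
        lo = float(w.samples.min()) if w.samples.size else -1.0
        hi = float(w.samples.max()) if w.samples.size else 1.0
        if hi - lo < 1e-12:
            lo, hi = lo - 1.0, hi + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        spr = int(round(w.rate * record_duration))
        padded = np.zeros(n_records * spr)
        padded[: w.samples.size] = w.samples
        dig = np.round((padded - lo) / (hi - lo) * 65535.0 - 32768.0)
        scaled.append(np.clip(dig, -32768, 32767).astype("<i2"))

    with open(path, "wb") as fh:
        fh.write(_ascii("0", 8))
        fh.write(_ascii(patient, 80))
        fh.write(_ascii(recording, 80))
        fh.write(_ascii("01.01.00", 8))
        fh.write(_ascii("00.00.00", 8))
        fh.write(_ascii(str(_EDF_HDR * (1 + ns)), 8))
        fh.write(_ascii("", 44))
        fh.write(_ascii(str(n_records), 8))
        fh.write(_ascii(f"{record_duration:g}", 8))
        fh.write(_ascii(str(ns), 4))
        for w in waveforms:
            fh.write(_ascii(w.label, 16))
        for _ in waveforms:
            fh.write(_ascii("", 80))  # transducer
        for _ in waveforms:
            fh.write(_ascii("", 8))  # physical dimension
        for lo in phys_min:
            fh.write(_ascii(f"{lo:.6g}"[:8], 8))
        for hi in phys_max:
            fh.write(_ascii(f"{hi:.6g}"[:8], 8))
        for _ in waveforms:
            fh.write(_ascii("-32768", 8))
        for _ in waveforms:
            fh.write(_ascii("32767", 8))
        for _ in waveforms:
            fh.write(_ascii("", 80))  # prefiltering
        for w in waveforms:
            fh.write(_ascii(str(int(round(w.rate * record_duration))), 8))
        for _ in waveforms:
            fh.write(_ascii("", 32))  # reserved
        spr = [int(round(w.rate * record_duration)) for w in waveforms]
        for r in range(n_records):
            for i in range(ns):
                fh.write(scaled[i][r * spr[i]: (r + 1) * spr[i]].tobytes())


def read_edf(path: str | Path) -> list[Waveform]:
    """Read a plain continuous EDF file into one Waveform per signal."""
    raw = Path(path).read_bytes()
    if len(raw) < _EDF_HDR:
        raise WaveformError("corrupt EDF header: file too short")

    def fld(off: int, width: int) -> str:
        return raw[off: off + width].decode("ascii", errors="replace").strip()

    try:
        n_records = int(fld(236, 8))
        record_duration = float(fld(244, 8))
        ns = int(fld(252, 4))
    except ValueError as exc:
        raise WaveformError(f"corrupt EDF header: {exc}") from exc
    if ns <= 0 or record_duration <= 0:
        raise WaveformError("corrupt EDF header: bad signal count or record duration")
    off = _EDF_HDR

    def col(width: int) -> list[str]:
        nonlocal off
        vals = [raw[off + i * width: off + (i + 1) * width].decode("ascii").strip()
                for i in range(ns)]
        off += ns * width
        return vals

    labels = col(16)
    col(80)  # transducer
    col(8)  # dimension
    pmin = [float(v) for v in col(8)]
    pmax = [float(v) for v in col(8)]
    dmin = [int(v) for v in col(8)]
    dmax = [int(v) for v in col(8)]
    col(80)  # prefiltering
    spr = [int(v) for v in col(8)]
    col(32)  # reserved

    data = np.frombuffer(raw[_EDF_HDR * (1 + ns):], dtype="<i2")
    rec_len = sum(spr)
    if data.size < n_records * rec_len:
        raise WaveformError("corrupt EDF: truncated data records")
    data = data[: n_records * rec_len].reshape(n_records, rec_len)
    out = []
    pos = 0
    for i in range(ns):
        dig = data[:, pos: pos + spr[i]].reshape(-1).astype(np.float64)
        pos += spr[i]
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        phys = pmin[i] + (dig - dmin[i]) * gain
        rate = spr[i] / record_duration
        if rate <= 0:
            raise WaveformError(f"corrupt EDF: rate <= 0 for signal {labels[i]!r}")
        out.append(Waveform(label=labels[i], rate=rate, samples=phys))
    return out


def read_waveform(path: str | Path, fmt: str | None = None) -> list[Waveform]:
    """Read waveform channel(s) from a file; format inferred from suffix if omitted."""
    p = Path(path)
    fmt = (fmt or p.suffix.lstrip(".")).lower()
    if fmt == "edf":
        return read_edf(p)
    if fmt == "csv":
        return [read_waveform_csv(p)]
    raise WaveformError(f"unsupported waveform format: {fmt!r}")
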