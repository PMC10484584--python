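"""Clock alignment of simultaneous recordings sharing a flow signal.

Two devices recording the same night disagree by a constant clock shift plus
a slow clock drift. Both are estimated from the per-window lag of the
normalized cross-correlation between the shared respiratory flow signals,
followed by a robust linear fit lag(t) = shift + drift * t over the windows
whose correlation peak is admissible. Recordings where too few windows
correlate are rejected as unalignable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sig
from scipy.stats import theilslopes

from .annotations import AnnotationSet, Hypnogram, ScoredEvent
from .waveio import Waveform


class AlignmentError(RuntimeError):
    """Raised when reliable time-alignment is not possible."""


@dataclass
class ClockModel:
    """Linear clock map: a time ``t`` on the target device corresponds to
    ``t * (1 + drift) + shift`` on the reference device."""

    shift: float
    drift: float
    window_lags: list[tuple[float, float, float]]  # (center, lag, peak corr)
    quality: float  # admissible fraction of windows

    def map_time(self, t):
        return np.asarray(t) * (1.0 + self.drift) + self.shift

    def inverse(self) -> "ClockModel":
        return ClockModel(shift=-self.shift / (1.0 + self.drift),
                          drift=1.0 / (1.0 + self.drift) - 1.0,
                          window_lags=[], quality=self.quality)


def _resample(w: Waveform, rate: float) -> np.ndarray:
    if w.rate == rate:
        return w.samples
    n_out = int(round(w.duration * rate))
    t_out = np.arange(n_out) / rate
    return np.interp(t_out, np.arange(w.samples.size) / w.rate, w.samples)


def windowed_xcorr(a: Waveform, b: Waveform, win: float = 120.0, step: float = 60.0,
                   rate: float = 10.0, max_lag: float = 60.0,
                   ) -> list[tuple[float, float, float]]:
    """Normalized cross-correlation peak lag per moving window.

    Returns (window center in ``b``-time, lag such that b(t) matches
    a(t + lag), peak correlation). Lags are refined to sub-sample precision
    by parabolic interpolation around the peak.
    """
    if win < 30:
        raise ValueError("window must be >= 30 s")
    xa = _resample(a, rate)
    xb = _resample(b, rate)
    n_win = int(round(win * rate))
    n_step = int(round(step * rate))
    n_lag = int(round(max_lag * rate))
    if xb.size < n_win or xa.size < n_win:
        raise AlignmentError("signals shorter than one correlation window")
    out = []
    for start in range(0, xb.size - n_win + 1, n_step):
        seg_b = xb[start: start + n_win]
        lo = max(0, start - n_lag)
        hi = min(xa.size, start + n_win + n_lag)
        seg_a = xa[lo:hi]
        seg_b = seg_b - seg_b.mean()
        seg_a = seg_a - seg_a.mean()
        denom_b = np.linalg.norm(seg_b)
        if denom_b == 0 or np.linalg.norm(seg_a) == 0:
            continue
        corr = sig.correlate(seg_a, seg_b, mode="valid", method="fft")
        # normalize by the local energy of the a-segment under each offset
        energy = sig.correlate(seg_a ** 2, np.ones(n_win), mode="valid", method="fft")
        norm = np.sqrt(np.maximum(energy, 1e-12)) * denom_b
        rho = corr / norm
        k = int(np.argmax(rho))
        peak = float(rho[k])
        # parabolic sub-sample refinement
        if 0 < k < rho.size - 1:
            y0, y1, y2 = rho[k - 1], rho[k], rho[k + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                k = k + 0.5 * (y0 - y2) / denom
        lag = (lo + k - start) / rate
        center = (start + n_win / 2.0) / rate
        out.append((center, float(lag), peak))
    return out


def fit_clock_model(lags: list[tuple[float, float, float]], *,
                    corr_threshold: float = 0.5, method: str = "lad",
                    max_drift: float = 0.01) -> ClockModel:
    """Robust linear fit of lag against window center time.

    ``method="lad"`` minimizes the absolute deviations (via iteratively
    reweighted least squares); ``method="theilsen"`` uses the median of
    pairwise slopes. Fewer than two admissible windows raise
    :class:`AlignmentError`.
    """
    ok = [(t, lag) for t, lag, rho in lags if rho >= corr_threshold]
    if len(ok) < 2:
        raise AlignmentError(
            f"only {len(ok)} window(s) with correlation >= {corr_threshold}; "
            "time-alignment not reliably possible")
    t = np.array([p[0] for p in ok])
    y = np.array([p[1] for p in ok])
    if method == "theilsen":
        drift, shift, *_ = theilslopes(y, t)
    elif method == "lad":
        X = np.column_stack([np.ones_like(t), t])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        for _ in range(50):
            r = np.abs(y - X @ beta)
            w = 1.0 / np.maximum(r, 1e-8)
            beta_new = np.linalg.lstsq(X * w[:, None] ** 0.5,
                                       y * w ** 0.5, rcond=None)[0]
            if np.max(np.abs(beta_new - beta)) < 1e-12:
                beta = beta_new
                break
            beta = beta_new
        shift, drift = beta
    else:
        raise ValueError(f"unknown fit method: {method!r}")
    if abs(drift) >= max_drift:
        raise AlignmentError(f"implausible clock drift {drift:.3g} (>= {max_drift})")
    quality = len(ok) / len(lags) if lags else 0.0
    return ClockModel(shift=float(shift), drift=float(drift),
                      window_lags=list(lags), quality=quality)


def apply_alignment(obj, m: ClockModel):
    """Map an object's timestamps through the clock model.

    Event onsets map as t -> t(1+drift)+shift and durations scale by
    (1+drift). Waveforms keep their samples and move their start/rate.
    """
    scale = 1.0 + m.drift
    if isinstance(obj, Waveform):
        return Waveform(label=obj.label, rate=obj.rate / scale,
                        samples=obj.samples, start=float(m.map_time(obj.start)))
    if isinstance(obj, ScoredEvent):
        return ScoredEvent(obj.etype, float(m.map_time(obj.onset)),
                           obj.duration * scale, obj.depth)
    if isinstance(obj, AnnotationSet):
        import math

        events = [apply_alignment(e, m) for e in obj.events]
        new_rec = float(m.map_time(obj.rec_duration))
        # keep the hypnogram's epoch count consistent with the mapped duration
        n_new = max(1, math.ceil(new_rec / 30.0))
        stages = list(obj.hypnogram.stages)
        stages = (stages + [stages[-1]] * n_new)[:n_new] if stages else ["W"] * n_new
        return AnnotationSet(hypnogram=Hypnogram(stages), events=events,
                             rec_duration=new_rec)
    raise TypeError(f"cannot align object of type {type(obj).__name__}")
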