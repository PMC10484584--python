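"""Two-phase training of the arousal network.

Phase 1 (``cardiac``) trains the cardiac feature extraction module alone to
regress the 2 Hz instantaneous heart rate from raw PPG (mean absolute error),
with temporal stretch/squeeze augmentation: a window is resampled by a factor
f and its IHR target divided by f, so the module sees a wide range of heart
rates regardless of the cohort's baseline.

Phase 2 (``end2end``) freezes the cardiac module (verified by parameter hash)
and trains the respiratory and arousal modules against 2 Hz binary cortical
arousal targets with class-weighted binary cross-entropy. Because the cardiac
module is frozen, its 2 Hz IHR output is precomputed once per record.

Losses are evaluated on the central part of each window only, so zero-padding
at the window edges never contaminates the targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..annotations import SubjectRecord
from .model import ArousalNet
from .ops import Adam, F32


@dataclass
class TrainConfig:
    phase: str = "cardiac"  # "cardiac" | "end2end"
    lr: float = 3e-3
    batch_size: int = 8
    window_s: int = 128  # batch window length, seconds
    steps_per_epoch: int = 60
    epochs: int = 8
    seed: int = 0
    stretch: float = 0.2  # augmentation range: f ~ U(1-stretch, 1+stretch)
    margin_s: float = 20.0  # edge margin excluded from the loss
    pos_weight: float = 6.0  # BCE weight on arousal-positive samples

    def __post_init__(self) -> None:
        if self.phase not in ("cardiac", "end2end"):
            raise ValueError(f"unknown training phase: {self.phase!r}")
        if not 0 <= self.stretch < 1:
            raise ValueError("stretch range must be symmetric around 1 and < 1")


@dataclass
class TrainLog:
    phase: str
    losses: list[float] = field(default_factory=list)
    cardiac_hash_before: str = ""
    cardiac_hash_after: str = ""


def stretch_targets(ihr: np.ndarray, factor: float) -> np.ndarray:
    """IHR target transformation under temporal stretch by ``factor``.

    Squeezing time by f (playing the signal back f times slower) divides the
    instantaneous rate by f: a 60 bpm segment at f = 0.8 becomes 75 bpm.
    """
    return ihr / factor


def arousal_target(rec: SubjectRecord, n_samples: int, rate: float = 2.0) -> np.ndarray:
    """2 Hz binary sequence marking cortical-arousal samples."""
    y = np.zeros(n_samples, dtype=F32)
    for ev in rec.psg_ref.events_of("arousal_cortical"):
        i0 = int(np.floor(ev.onset * rate))
        i1 = int(np.ceil(ev.end * rate))
        y[max(i0, 0): min(i1, n_samples)] = 1.0
    return y


def _require_sleep_data(cohort: list[SubjectRecord]) -> None:
    if not cohort or all(r.psg_ref.tst == 0 for r in cohort):
        raise ValueError("training requires sleep-period data")


def _cardiac_batch(model: ArousalNet, cohort, tc: TrainConfig,
                   rng: np.random.Generator):
    """Sample stretch-augmented (PPG window, IHR target) pairs."""
    L = tc.window_s
    xs, ys = [], []
    for _ in range(tc.batch_size):
        rec = cohort[rng.integers(len(cohort))]
        ppg = rec.waveforms["ppg"].samples
        ihr = rec.ihr_ref.samples
        f = 1.0 + (rng.uniform(-tc.stretch, tc.stretch) if tc.stretch else 0.0)
        src_s = L / f
        t0 = rng.uniform(0, max(ppg.size / 100.0 - src_s, 0))
        # resample the source span [t0, t0 + L/f) onto an L-second window
        t_out = t0 + np.arange(L * 100) / (100.0 * f)
        x = np.interp(t_out, np.arange(ppg.size) / 100.0, ppg)
        t_out2 = t0 + np.arange(L * 2) / (2.0 * f)
        y = stretch_targets(np.interp(t_out2, np.arange(ihr.size) / 2.0, ihr), f)
        xs.append(x)
        ys.append(y)
    return (np.asarray(xs, dtype=F32)[:, None, :],
            np.asarray(ys, dtype=F32)[:, None, :])


def cardiac_mae(model: ArousalNet, cohort, chunk_s: int = 600) -> float:
    """Full-record IHR mean absolute error (bpm) over a cohort."""
    errs = []
    for rec in cohort:
        ppg = rec.waveforms["ppg"].samples
        n_sec = int(ppg.size // 100)
        pred = predict_ihr(model, ppg[: n_sec * 100], chunk_s=chunk_s)
        truth = rec.ihr_ref.samples[: pred.size]
        errs.append(np.abs(pred[: truth.size] - truth))
    return float(np.mean(np.concatenate(errs)))


def predict_ihr(model: ArousalNet, ppg: np.ndarray, chunk_s: int = 600,
                overlap_s: int = 60) -> np.ndarray:
    """Chunked full-record cardiac forward pass (2 Hz IHR)."""
    n_sec = int(len(ppg) // 100)
    out = np.empty(n_sec * 2, dtype=F32)
    t = 0
    while t < n_sec:
        t0 = max(0, t - overlap_s)
        t1 = min(n_sec, t + chunk_s)
        seg = ppg[t0 * 100: t1 * 100]
        ihr = model.forward_cardiac(np.asarray(seg, dtype=F32)[None, None, :])[0, 0]
        out[t * 2: t1 * 2] = ihr[(t - t0) * 2:]
        t = t1
    return out


def train_cardiac(model: ArousalNet, cohort: list[SubjectRecord],
                  tc: TrainConfig) -> TrainLog:
    """Phase-1 training of the cardiac module (IHR regression, MAE loss)."""
    if tc.phase != "cardiac":
        raise ValueError("TrainConfig.phase must be 'cardiac'")
    _require_sleep_data(cohort)
    rng = np.random.default_rng(tc.seed)
    opt = Adam(model.cardiac_params(), lr=tc.lr)
    log = TrainLog(phase="cardiac")
    margin = int(tc.margin_s * 2)
    for _epoch in range(tc.epochs):
        for _step in range(tc.steps_per_epoch):
            x, y = _cardiac_batch(model, cohort, tc, rng)
            pred = model.forward_cardiac(x)
            core = slice(margin, pred.shape[2] - margin)
            diff = pred[:, :, core] - y[:, :, core]
            n = diff.size
            loss = float(np.abs(diff).mean())
            gpred = np.zeros_like(pred)
            gpred[:, :, core] = np.sign(diff) / n
            opt.zero_grad()
            model.cardiac.backward(gpred)
            opt.step()
            log.losses.append(loss)
    return log


def train_end2end(model: ArousalNet, cohort: list[SubjectRecord],
                  tc: TrainConfig) -> TrainLog:
    """Phase-2 training: frozen cardiac module, arousal targets, weighted BCE."""
    if tc.phase != "end2end":
        raise ValueError("TrainConfig.phase must be 'end2end'")
    _require_sleep_data(cohort)
    if all(len(r.psg_ref.events_of("arousal_cortical")) == 0 for r in cohort):
        raise ValueError("cohort contains no cortical arousal labels")
    rng = np.random.default_rng(tc.seed)
    opt = Adam(model.detector_params(), lr=tc.lr)
    log = TrainLog(phase="end2end",
                   cardiac_hash_before=model.cardiac_hash())

    # cardiac module is frozen: precompute its IHR once per record
    ihr_est, flows, targets = [], [], []
    for rec in cohort:
        ppg = rec.waveforms["ppg"].samples
        n_sec = int(min(ppg.size // 100, rec.waveforms["flow"].samples.size // 10))
        ihr_est.append(predict_ihr(model, ppg[: n_sec * 100]))
        flows.append(rec.waveforms["flow"].samples[: n_sec * 10].astype(F32))
        targets.append(arousal_target(rec, n_sec * 2))

    L = tc.window_s
    margin = int(tc.margin_s * 2)
    eps = 1e-7
    for _epoch in range(tc.epochs):
        for _step in range(tc.steps_per_epoch):
            bi, bf, by = [], [], []
            for _ in range(tc.batch_size):
                s = rng.integers(len(cohort))
                n_sec = flows[s].size // 10
                t0 = int(rng.integers(0, max(n_sec - L, 1)))
                bi.append(ihr_est[s][t0 * 2: (t0 + L) * 2])
                bf.append(flows[s][t0 * 10: (t0 + L) * 10])
                by.append(targets[s][t0 * 2: (t0 + L) * 2])
            ihr = np.asarray(bi, dtype=F32)[:, None, :]
            flow = np.asarray(bf, dtype=F32)[:, None, :]
            y = np.asarray(by, dtype=F32)[:, None, :]
            p = model.forward_detector(ihr, flow)
            core = slice(margin, p.shape[2] - margin)
            pc = np.clip(p[:, :, core], eps, 1 - eps)
            yc = y[:, :, core]
            w = np.where(yc > 0.5, tc.pos_weight, 1.0)
            n = yc.size
            loss = float((-w * (yc * np.log(pc) + (1 - yc) * np.log(1 - pc))).mean())
            gp = np.zeros_like(p)
            gp[:, :, core] = w * (pc - yc) / (pc * (1 - pc)) / n
            opt.zero_grad()
            model.backward_detector(gp)
            opt.step()
            log.losses.append(loss)
    log.cardiac_hash_after = model.cardiac_hash()
    assert log.cardiac_hash_before == log.cardiac_hash_after
    return log
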