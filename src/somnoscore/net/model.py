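"""The autonomic arousal detection network.

Three modules built from residual dilated-convolution blocks:

* a cardiac feature extraction module (4 blocks + 3 dense layers) mapping
  100 Hz PPG to a 2 Hz instantaneous heart rate (IHR) estimate — IHR is the
  *only* cardiac feature passed on, making the architecture agnostic to the
  cardiac sensor;
* a respiratory module (1 block) mapping 10 Hz flow to 2 Hz features;
* an arousal module (3 blocks without further pooling + 2 dense layers +
  sigmoid) combining the normalized IHR with the respiratory features into a
  2 Hz arousal probability.

The default configuration has a total receptive field of ~85 s (roughly
±45 s of temporal context) and cumulative pooling that lands exactly on the
2 Hz output rate from both the 100 Hz and the 10 Hz input path.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, asdict
from math import prod
from pathlib import Path

import numpy as np
from scipy import signal as sig

from ..waveio import Waveform
from ..events import ProbabilitySeries
from .ops import Adam, Conv1d, F32, Param, ReLU, ResBlock, Sequential, Sigmoid, params_hash


# ---------------------------------------------------------------------------
# preprocessing

def _highpass(w: Waveform, target_rate: float, cutoff: float) -> Waveform:
    """Resample to the target rate, then zero-phase high-pass filter."""
    if w.samples.size == 0:
        raise ValueError("empty waveform")
    x = w.samples
    if w.rate != target_rate:
        up = int(round(target_rate * 1000))
        down = int(round(w.rate * 1000))
        g = np.gcd(up, down)
        x = sig.resample_poly(x, up // g, down // g)
        n_target = int(round(w.duration * target_rate))
        x = x[:n_target] if x.size >= n_target else np.pad(x, (0, n_target - x.size))
    sos = sig.butter(2, cutoff, btype="highpass", fs=target_rate, output="sos")
    y = sig.sosfiltfilt(sos, x)
    return Waveform(label=w.label, rate=target_rate, samples=y, start=w.start)


def preprocess_ppg(w: Waveform) -> Waveform:
    """PPG conditioning: resample to 100 Hz, 0.3 Hz zero-phase high-pass."""
    return _highpass(w, 100.0, 0.3)


def preprocess_flow(w: Waveform) -> Waveform:
    """Flow conditioning: resample to 10 Hz, 0.03 Hz zero-phase high-pass."""
    return _highpass(w, 10.0, 0.03)


# ---------------------------------------------------------------------------
# configuration

@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults are CPU-scale)."""

    ppg_rate: float = 100.0
    flow_rate: float = 10.0
    out_rate: float = 2.0
    kernel: int = 3
    cardiac_channels: tuple[int, ...] = (8, 16, 16, 24)
    cardiac_pools: tuple[int, ...] = (5, 5, 2, 1)
    cardiac_dilations: tuple[tuple[int, ...], ...] = ((1, 2, 4, 8),) * 4
    cardiac_dense: tuple[int, ...] = (16, 8, 1)
    flow_channels: tuple[int, ...] = (8,)
    flow_pools: tuple[int, ...] = (5,)
    flow_dilations: tuple[tuple[int, ...], ...] = ((1, 2, 4, 8),)
    arousal_channels: tuple[int, ...] = (16, 16, 16)
    arousal_dilations: tuple[tuple[int, ...], ...] = ((1, 2, 4, 8), (1, 2, 4, 8),
                                                      (1, 2, 4, 8, 16))
    arousal_dense: tuple[int, ...] = (16, 1)
    ihr_offset: float = 60.0  # bpm; IHR normalization for the arousal head
    ihr_scale: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if prod(self.cardiac_pools) != int(self.ppg_rate / self.out_rate):
            raise ValueError(
                f"cardiac pooling {self.cardiac_pools} does not map "
                f"{self.ppg_rate} Hz to {self.out_rate} Hz")
        if prod(self.flow_pools) != int(self.flow_rate / self.out_rate):
            raise ValueError(
                f"flow pooling {self.flow_pools} does not map "
                f"{self.flow_rate} Hz to {self.out_rate} Hz")
        rf = self.receptive_field_s()
        if not 80.0 <= rf <= 100.0:
            raise ValueError(f"total receptive field {rf:.1f} s outside [80, 100] s")

    def _path_rf(self, dilations, pools, rate) -> float:
        rf = 0.0
        for dils, pool in zip(dilations, pools):
            rf += (self.kernel - 1) * sum(dils) / rate
            rate /= pool
        return rf

    def receptive_field_s(self) -> float:
        """Total temporal context (seconds) along the deepest (PPG) path."""
        cardiac = self._path_rf(self.cardiac_dilations, self.cardiac_pools, self.ppg_rate)
        arousal = self._path_rf(self.arousal_dilations,
                                (1,) * len(self.arousal_dilations), self.out_rate)
        return cardiac + arousal

    @property
    def input_granule(self) -> int:
        """Window lengths must be multiples of this many seconds."""
        return 1  # 100 samples PPG, 10 flow, 2 output per second


def small_config(**overrides) -> ModelConfig:
    """A reduced configuration for fast bookkeeping tests."""
    cfg = ModelConfig(
        cardiac_channels=(4, 4, 6, 6), cardiac_dense=(6, 4, 1),
        flow_channels=(4,), arousal_channels=(6, 6, 6), arousal_dense=(6, 1),
        **overrides)
    return cfg


# ---------------------------------------------------------------------------
# the network

class ArousalNet:
    """PPG + flow -> (IHR @ 2 Hz, arousal probability @ 2 Hz)."""

    def __init__(self, cfg: ModelConfig | None = None):
        self.cfg = cfg = cfg or ModelConfig()
        cfg.validate()
        rng = np.random.default_rng(cfg.seed)

        def blocks(c_in, channels, dilations, pools):
            out = []
            for c, dils, pool in zip(channels, dilations, pools):
                out.append(ResBlock(c_in, c, dils, cfg.kernel, pool, rng))
                c_in = c
            return out, c_in

        cardiac_blocks, c = blocks(1, cfg.cardiac_channels, cfg.cardiac_dilations,
                                   cfg.cardiac_pools)
        head = []
        for i, c_out in enumerate(cfg.cardiac_dense):
            head.append(Conv1d(c, c_out, 1, rng=rng))
            if i < len(cfg.cardiac_dense) - 1:
                head.append(ReLU())
            c = c_out
        # bias the IHR head toward a plausible resting heart rate
        head[-1].b.value[:] = cfg.ihr_offset
        self.cardiac = Sequential(cardiac_blocks + head)

        flow_blocks, c_flow = blocks(1, cfg.flow_channels, cfg.flow_dilations,
                                     cfg.flow_pools)
        self.flow = Sequential(flow_blocks)

        arousal_blocks, c = blocks(1 + c_flow, cfg.arousal_channels,
                                   cfg.arousal_dilations,
                                   (1,) * len(cfg.arousal_channels))
        head = []
        for i, c_out in enumerate(cfg.arousal_dense):
            head.append(Conv1d(c, c_out, 1, rng=rng))
            if i < len(cfg.arousal_dense) - 1:
                head.append(ReLU())
            c = c_out
        head.append(Sigmoid())
        self.arousal = Sequential(arousal_blocks + head)
        self._n_flow_ch = c_flow

    # -- parameter groups -------------------------------------------------
    def cardiac_params(self) -> list[Param]:
        return self.cardiac.params()

    def detector_params(self) -> list[Param]:
        return self.flow.params() + self.arousal.params()

    def cardiac_hash(self) -> str:
        return params_hash(self.cardiac_params())

    # -- forward passes ----------------------------------------------------
    def forward_cardiac(self, ppg: np.ndarray) -> np.ndarray:
        """(B, 1, T@100 Hz) -> IHR (B, 1, T@2 Hz)."""
        return self.cardiac.forward(ppg.astype(F32))

    def forward_detector(self, ihr: np.ndarray, flow: np.ndarray) -> np.ndarray:
        """(B, 1, T@2 Hz) IHR + (B, 1, T@10 Hz) flow -> probability (B, 1, T@2 Hz)."""
        feats = self.flow.forward(flow.astype(F32))
        ihr_n = (ihr.astype(F32) - self.cfg.ihr_offset) / self.cfg.ihr_scale
        x = np.concatenate([ihr_n, feats], axis=1)
        return self.arousal.forward(x)

    def backward_detector(self, gprob: np.ndarray) -> None:
        gx = self.arousal.backward(gprob.astype(F32))
        self.flow.backward(gx[:, 1:, :])

    def forward(self, ppg: np.ndarray, flow: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ihr = self.forward_cardiac(ppg)
        prob = self.forward_detector(ihr, flow)
        return ihr, prob

    # -- inference ---------------------------------------------------------
    def predict(self, ppg: Waveform, flow: Waveform) -> tuple[ProbabilitySeries, Waveform]:
        """Run the full model over preprocessed, co-covering inputs.

        Returns the 2 Hz arousal probability series and the 2 Hz IHR trace
        over the common interval of the two channels.
        """
        if ppg.rate != self.cfg.ppg_rate or flow.rate != self.cfg.flow_rate:
            raise ValueError(
                f"expected rates ({self.cfg.ppg_rate}, {self.cfg.flow_rate}) Hz, "
                f"got ({ppg.rate}, {flow.rate})")
        start = max(ppg.start, flow.start)
        stop = min(ppg.start + ppg.duration, flow.start + flow.duration)
        n_sec = int((stop - start))
        if n_sec <= 0:
            raise ValueError("inputs have no overlapping interval")
        i_p = int(round((start - ppg.start) * ppg.rate))
        i_f = int(round((start - flow.start) * flow.rate))
        x_p = ppg.samples[i_p: i_p + n_sec * 100]
        x_f = flow.samples[i_f: i_f + n_sec * 10]
        ihr, prob = self.forward(x_p[None, None, :], x_f[None, None, :])
        series = ProbabilitySeries(np.clip(prob[0, 0], 0.0, 1.0), start=start)
        ihr_w = Waveform(label="IHR_est", rate=2.0, samples=ihr[0, 0].astype(float),
                         start=start)
        return series, ihr_w

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        state = {
            "config": asdict(self.cfg),
            "cardiac": [p.value for p in self.cardiac_params()],
            "detector": [p.value for p in self.detector_params()],
        }
        with open(path, "wb") as fh:
            pickle.dump(state, fh)

    @classmethod
    def load(cls, path: str | Path) -> "ArousalNet":
        with open(path, "rb") as fh:
            state = pickle.load(fh)
        cfg_dict = state["config"]
        for key in ("cardiac_channels", "cardiac_pools", "cardiac_dense",
                    "flow_channels", "flow_pools", "arousal_channels",
                    "arousal_dense"):
            cfg_dict[key] = tuple(cfg_dict[key])
        for key in ("cardiac_dilations", "flow_dilations", "arousal_dilations"):
            cfg_dict[key] = tuple(tuple(d) for d in cfg_dict[key])
        model = cls(ModelConfig(**cfg_dict))
        for p, v in zip(model.cardiac_params(), state["cardiac"]):
            p.value[...] = v
        for p, v in zip(model.detector_params(), state["detector"]):
            p.value[...] = v
        return model
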