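"""Minimal CPU tensor layers for 1-D dilated convolutional networks.

Arrays are float32 with shape (batch, channels, time). Each layer caches what
its backward pass needs; a training step is forward -> backward -> Adam. This
is deliberately a small, deterministic engine sized for the desk-scale
networks used here, not a general autodiff framework.
"""

from __future__ import annotations

import hashlib

import numpy as np

F32 = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(F32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv1d(Layer):
    """Dilated 1-D convolution with centered zero padding (odd kernels)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (c_in * kernel))
        self.W = Param(rng.normal(0.0, std, size=(c_out, c_in, kernel)))
        self.b = Param(np.zeros(c_out))
        self.kernel = kernel
        self.dilation = dilation
        self._xp: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        d, k = self.dilation, self.kernel
        pad = d * (k // 2)
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad))) if pad else x
        self._xp = xp
        T = x.shape[2]
        W = self.W.value
        y = np.einsum("oi,bit->bot", W[:, :, 0], xp[:, :, : T], optimize=True)
        for j in range(1, k):
            y += np.einsum("oi,bit->bot", W[:, :, j], xp[:, :, j * d: j * d + T],
                           optimize=True)
        return y + self.b.value[None, :, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        d, k = self.dilation, self.kernel
        pad = d * (k // 2)
        xp = self._xp
        T = gy.shape[2]
        self.b.grad += gy.sum(axis=(0, 2))
        gxp = np.zeros_like(xp)
        W = self.W.value
        for j in range(k):
            sl = slice(j * d, j * d + T)
            self.W.grad[:, :, j] += np.einsum("bot,bit->oi", gy, xp[:, :, sl],
                                              optimize=True)
            gxp[:, :, sl] += np.einsum("oi,bot->bit", W[:, :, j], gy, optimize=True)
        return gxp[:, :, pad: pad + T] if pad else gxp


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        # numerically stable in both tails
        self._y = np.where(x >= 0,
                           1.0 / (1.0 + np.exp(-np.abs(x))),
                           np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        return self._y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._y * (1.0 - self._y)


class MaxPool(Layer):
    def __init__(self, factor: int):
        self.factor = factor

    def forward(self, x: np.ndarray) -> np.ndarray:
        f = self.factor
        if f == 1:
            self._shape = None
            return x
        B, C, T = x.shape
        if T % f:
            raise ValueError(f"time axis {T} not divisible by pool factor {f}")
        xr = x.reshape(B, C, T // f, f)
        self._arg = xr.argmax(axis=3)
        self._shape = xr.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=3)[..., 0]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self.factor == 1 or self._shape is None:
            return gy
        gx = np.zeros(self._shape, dtype=gy.dtype)
        np.put_along_axis(gx, self._arg[..., None], gy[..., None], axis=3)
        B, C, Tf, f = self._shape
        return gx.reshape(B, C, Tf * f)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


class ResBlock(Layer):
    """Stacked dilated convolutions with a residual skip, a 1x1 dense
    projection, and temporal max pooling."""

    def __init__(self, c_in: int, c_out: int, dilations: tuple[int, ...],
                 kernel: int, pool: int, rng: np.random.Generator):
        self.convs: list[Layer] = []
        c = c_in
        for d in dilations:
            self.convs.append(Conv1d(c, c_out, kernel, dilation=d, rng=rng))
            self.convs.append(ReLU())
            c = c_out
        self.proj = Conv1d(c_in, c_out, 1, rng=rng) if c_in != c_out else None
        self.dense = Conv1d(c_out, c_out, 1, rng=rng)
        self.relu = ReLU()
        self.pool = MaxPool(pool)

    def params(self) -> list[Param]:
        ps = [p for layer in self.convs for p in layer.params()]
        if self.proj is not None:
            ps += self.proj.params()
        return ps + self.dense.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = x
        for layer in self.convs:
            h = layer.forward(h)
        skip = self.proj.forward(x) if self.proj is not None else x
        z = h + skip
        return self.pool.forward(self.relu.forward(self.dense.forward(z)))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gz = self.dense.backward(self.relu.backward(self.pool.backward(gy)))
        gh = gz
        gskip = self.proj.backward(gz) if self.proj is not None else gz
        for layer in reversed(self.convs):
            gh = layer.backward(gh)
        return gh + gskip

    def receptive_field(self, kernel: int | None = None) -> int:
        """Receptive field in input samples contributed by the conv stack."""
        taps = sum((c.kernel - 1) * c.dilation
                   for c in self.convs if isinstance(c, Conv1d))
        return taps + 1


class Adam:
    def __init__(self, params: list[Param], lr: float = 3e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def params_hash(params: list[Param]) -> str:
    h = hashlib.sha256()
    for p in params:
        h.update(np.ascontiguousarray(p.value).tobytes())
    return h.hexdigest()


def params_state(params: list[Param]) -> list[np.ndarray]:
    return [p.value.copy() for p in params]


def load_params_state(params: list[Param], state: list[np.ndarray]) -> None:
    for p, s in zip(params, state):
        p.value[...] = s
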