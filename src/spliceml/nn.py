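"""A compact NumPy engine for 1-D dilated convolutional networks.

Activations are kept channel-last, shape ``(batch, length, channels)``,
float32, so every convolution reduces to a handful of BLAS matrix products
(one per kernel tap).  Each layer implements ``forward``/``backward`` and
exposes its parameters through :class:`Param` objects carrying the value
and accumulated gradient.  The only optimizer provided is AdamW with
decoupled weight decay, driven by an externally supplied learning-rate
schedule (cosine annealing with warm restarts).

This is deliberately a minimal engine: no graph tracing, no broadcasting
rules -- just the layers the splice models need, with deterministic,
seedable initialization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


class Param:
    """A trainable array with its gradient and weight-decay flag."""

    __slots__ = ("data", "grad", "decay", "name")

    def __init__(self, data: np.ndarray, decay: bool, name: str = ""):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.decay = decay
        self.name = name


class Conv1d:
    """Dilated 1-D convolution with 'same' zero padding.

    Weight shape ``(kernel, c_in, c_out)``; forward is a sum of ``kernel``
    matmuls over shifted views of the padded input.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int,
                 rng: np.random.Generator, name: str = "conv"):
        if kernel % 2 == 0:
            raise ValueError("kernel width must be odd for 'same' padding")
        scale = math.sqrt(2.0 / (c_in * kernel))  # He initialization
        self.W = Param(rng.normal(0.0, scale, (kernel, c_in, c_out)),
                       decay=True, name=f"{name}.W")
        self.b = Param(np.zeros(c_out), decay=False, name=f"{name}.b")
        self.dilation = dilation
        self._xp: np.ndarray | None = None

    @property
    def pad(self) -> int:
        return self.dilation * (self.W.data.shape[0] - 1) // 2

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k = self.W.data.shape[0]
        d, p = self.dilation, self.pad
        B, L, _ = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (0, 0))) if p else x
        y = np.empty((B, L, self.W.data.shape[2]), dtype=np.float32)
        y[:] = self.b.data
        for j in range(k):
            y += xp[:, j * d: j * d + L, :] @ self.W.data[j]
        self._xp = xp if train else None
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        assert xp is not None, "backward before forward(train=True)"
        k = self.W.data.shape[0]
        d, p = self.dilation, self.pad
        B, L, _ = dy.shape
        dxp = np.zeros_like(xp)
        for j in range(k):
            sl = xp[:, j * d: j * d + L, :]
            self.W.grad[j] += np.einsum("blc,blo->co", sl, dy, optimize=True)
            dxp[:, j * d: j * d + L, :] += dy @ self.W.data[j].T
        self.b.grad += dy.sum(axis=(0, 1))
        self._xp = None
        return dxp[:, p: p + L, :] if p else dxp

    def params(self) -> list[Param]:
        return [self.W, self.b]


class BatchNorm1d:
    """Batch normalization over (batch, length) per channel."""

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5, name: str = "bn"):
        self.gamma = Param(np.ones(channels), decay=False, name=f"{name}.g")
        self.beta = Param(np.zeros(channels), decay=False, name=f"{name}.b")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._cache = (xhat, inv, x.shape[0] * x.shape[1])
        return self.gamma.data * xhat + self.beta.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, n = self._cache
        self._cache = None
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1))
        self.beta.grad += dy.sum(axis=(0, 1))
        dxhat = dy * self.gamma.data
        dx = (dxhat - dxhat.mean(axis=(0, 1))
              - xhat * (dxhat * xhat).mean(axis=(0, 1))) * inv
        return dx.astype(np.float32, copy=False)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx

    def params(self) -> list[Param]:
        return []


class PreActUnit:
    """BN -> ReLU -> dilated conv, the building unit of a residual block."""

    def __init__(self, channels: int, kernel: int, dilation: int,
                 rng: np.random.Generator, name: str):
        self.bn = BatchNorm1d(channels, name=f"{name}.bn")
        self.act = ReLU()
        self.conv = Conv1d(channels, channels, kernel, dilation, rng,
                           name=f"{name}.conv")

    def forward(self, x, train):
        return self.conv.forward(self.act.forward(self.bn.forward(x, train),
                                                  train), train)

    def backward(self, dy):
        return self.bn.backward(self.act.backward(self.conv.backward(dy)))

    def params(self):
        return self.bn.params() + self.conv.params()


class ResidualBlock:
    """Two pre-activation units with an identity shortcut."""

    def __init__(self, channels: int, kernel: int, dilation: int,
                 rng: np.random.Generator, name: str):
        self.u1 = PreActUnit(channels, kernel, dilation, rng, f"{name}.u1")
        self.u2 = PreActUnit(channels, kernel, dilation, rng, f"{name}.u2")

    def forward(self, x, train):
        return x + self.u2.forward(self.u1.forward(x, train), train)

    def backward(self, dy):
        return dy + self.u1.backward(self.u2.backward(dy))

    def params(self):
        return self.u1.params() + self.u2.params()


# ---------------------------------------------------------------------------
# Optimizer and learning-rate schedule
# ---------------------------------------------------------------------------

class AdamW:
    """AdamW with decoupled weight decay applied to decay-flagged params."""

    def __init__(self, params: list[Param], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad * p.grad - v)
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if p.decay and self.weight_decay:
                update = update + self.weight_decay * p.data
            p.data -= lr * update


def warm_restart_lr(t: float, cycles: tuple[int, ...], lr0: float) -> float:
    """Cosine-annealed learning rate with warm restarts.

    ``t`` is a continuous epoch index.  Within each cycle of length ``c``
    the rate starts at ``lr0`` and decays to exactly 0 at the cycle end:
    ``lr(t) = lr0 * (1 + cos(pi * u)) / 2`` with ``u`` the position within
    the cycle.  Past the last cycle the rate is 0.
    """
    start = 0.0
    for c in cycles:
        if t < start + c:
            u = (t - start) / c
            return lr0 * 0.5 * (1.0 + math.cos(math.pi * u))
        start += c
    return 0.0


def cycle_step_lrs(cycle_epochs: int, steps_per_epoch: int, lr0: float
                   ) -> np.ndarray:
    """Per-step learning rates for one warm-restart cycle.

    The first step runs at exactly ``lr0`` and the last step of the cycle
    at exactly 0, with cosine annealing in between.
    """
    n = cycle_epochs * steps_per_epoch
    if n == 1:
        return np.array([lr0])
    u = np.arange(n) / (n - 1)
    return lr0 * 0.5 * (1.0 + np.cos(np.pi * u))


def softmax_pairs(z: np.ndarray) -> np.ndarray:
    """Stable softmax over adjacent channel pairs (..., 2k) -> (..., 2k)."""
    shape = z.shape
    pairs = z.reshape(*shape[:-1], shape[-1] // 2, 2)
    pairs = pairs - pairs.max(axis=-1, keepdims=True)
    e = np.exp(pairs)
    return (e / e.sum(axis=-1, keepdims=True)).reshape(shape)


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
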