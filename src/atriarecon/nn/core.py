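"""Minimal NumPy neural-network layers with hand-written backprop.

Only what the reconstruction models need: dense layers, 3D convolutions,
max-pooling, learned upsampling, batch normalization, dropout, and Adam.
Every layer caches its forward inputs and exposes ``backward`` returning
the gradient w.r.t. its input while accumulating parameter gradients.
Correctness is pinned down by numerical gradient checks in the tests.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray, dtype=None):
        self.value = np.asarray(value, dtype=dtype or np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        # bias correction folded into the step size (fewer temporaries)
        alpha = self.lr * np.sqrt(1.0 - b2**self.t) / (1.0 - b1**self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * np.square(p.grad)
            denom = np.sqrt(v)
            denom += self.eps
            p.value -= alpha * m / denom

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Dense:
    """Affine map (B, n_in) -> (B, n_out), optionally with external weights."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)  # He init for the ReLU stack
        self.W = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class BatchNorm:
    """Batch normalization over all axes except ``channel_axis``.

    Works for dense activations (B, C) with channel_axis=1 and for
    volumetric activations (B, C, D, H, W).  Running statistics use
    momentum 0.1; eps 1e-5.
    """

    def __init__(self, n_channels: int, channel_axis: int = 1,
                 momentum: float = 0.1, eps: float = 1e-5, dtype=None):
        dtype = dtype or np.float64
        self.axis = channel_axis
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(np.ones(n_channels), dtype)
        self.beta = Param(np.zeros(n_channels), dtype)
        self.running_mean = np.zeros(n_channels, dtype=dtype)
        self.running_var = np.ones(n_channels, dtype=dtype)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def _shape(self, ndim: int) -> tuple[int, ...]:
        s = [1] * ndim
        s[self.axis] = -1
        return tuple(s)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = tuple(i for i in range(x.ndim) if i != self.axis)
        shp = self._shape(x.ndim)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            n = x.size // x.shape[self.axis]
            self.running_mean += self.momentum * (mean - self.running_mean)
            unbiased = var * n / max(n - 1, 1)
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shp)) * inv.reshape(shp)
        self._cache = (xhat, inv, axes, shp, training)
        return self.gamma.value.reshape(shp) * xhat + self.beta.value.reshape(shp)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, axes, shp, training = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.value.reshape(shp)
        if not training:
            return dxhat * inv.reshape(shp)
        n = dout.size // dout.shape[self.axis]
        term = (
            dxhat
            - dxhat.mean(axis=axes).reshape(shp)
            - xhat * (dxhat * xhat).mean(axis=axes).reshape(shp)
        )
        return term * inv.reshape(shp)


class Dropout:
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x: np.ndarray, training: bool,
                rng: np.random.Generator | None) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


def _conv3d(x: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Same-padding stride-1 3D correlation: (B,Ci,D,H,W) x (Co,Ci,k,k,k)."""
    k = W.shape[-1]
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    return np.einsum("bcxyzijk,ocijk->boxyz", win, W, optimize=True)


class Conv3d:
    """Same-padding stride-1 3D convolution with odd kernel size."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        fan_in = c_in * kernel**3
        scale = np.sqrt(2.0 / fan_in)
        self.W = Param(rng.normal(0.0, scale, size=(c_out, c_in, kernel, kernel, kernel)))
        self.b = Param(np.zeros(c_out))
        self._x = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        out = _conv3d(x, self.W.value)
        return out + self.b.value[None, :, None, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k = self.W.value.shape[-1]
        p = k // 2
        xp = np.pad(self._x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
        self.W.grad += np.einsum("bcxyzijk,boxyz->ocijk", win, dout, optimize=True)
        self.b.grad += dout.sum(axis=(0, 2, 3, 4))
        # input gradient = correlation of dout with the flipped, transposed kernel
        Wflip = self.W.value[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        return _conv3d(dout, Wflip)


class MaxPool3d:
    """Non-overlapping 2x2x2 max pooling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError("spatial dims must be even for 2x pooling")
        xr = x.reshape(b, c, d // 2, 2, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5, 7))
        self._mask = xr == out[:, :, :, None, :, None, :, None]
        self._shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        spread = self._mask * dout[:, :, :, None, :, None, :, None]
        # split gradient evenly among tied maxima
        counts = self._mask.sum(axis=(3, 5, 7))[:, :, :, None, :, None, :, None]
        return (spread / counts).reshape(self._shape)


class UpConv3d:
    """Learned 2x upsampling (transposed convolution, kernel 2, stride 2)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / c_in)
        self.W = Param(rng.normal(0.0, scale, size=(c_in, c_out, 2, 2, 2)))
        self.b = Param(np.zeros(c_out))
        self._x = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        b, c, d, h, w = x.shape
        out = np.einsum("bcxyz,coijk->boxiyjzk", x, self.W.value, optimize=True)
        out = out.reshape(b, -1, 2 * d, 2 * h, 2 * w)
        return out + self.b.value[None, :, None, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, co, d2, h2, w2 = dout.shape
        dr = dout.reshape(b, co, d2 // 2, 2, h2 // 2, 2, w2 // 2, 2)
        dr = dr.transpose(0, 1, 2, 4, 6, 3, 5, 7)  # b,o,x,y,z,i,j,k
        self.W.grad += np.einsum("boxyzijk,bcxyz->coijk", dr, self._x, optimize=True)
        self.b.grad += dout.sum(axis=(0, 2, 3, 4))
        return np.einsum("boxyzijk,coijk->bcxyz", dr, self.W.value, optimize=True)
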