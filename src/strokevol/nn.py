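"""Minimal CPU neural-network layers with explicit backward passes.

This is a small, self-contained layer stack (2D/3D convolution, batch
normalization, ReLU, 2x max pooling, 2x transposed convolution, Adam) built
on numpy, sized for the compact encoder-decoder models this package trains.
Activations are kept channels-last internally, so every convolution reduces
to one matrix product per kernel offset and runs on BLAS.

All layers expose ``forward(x, train)`` and ``backward(dout)``; parameters
are :class:`Param` objects holding value and accumulated gradient.  The
gradients are verified against numerical differentiation in the test suite.
"""

from __future__ import annotations

from itertools import product as _iterproduct

import numpy as np

__all__ = [
    "Param",
    "Conv",
    "BatchNorm",
    "ReLU",
    "MaxPool2",
    "UpConv2",
    "Adam",
    "sigmoid",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _spatial_slices(offset, spatial):
    return tuple(slice(o, o + s) for o, s in zip(offset, spatial))


class Conv(Layer):
    """'Same' convolution with a 3^nd kernel, stride 1, zero padding 1.

    Weights are stored per kernel offset as (Cin, Cout) matrices so the
    forward pass is a sum of 3^nd BLAS products over shifted views.
    """

    def __init__(self, in_ch: int, out_ch: int, ndim: int, rng: np.random.Generator,
                 kernel: int = 3):
        if kernel % 2 != 1:
            raise ValueError("kernel must be odd")
        self.ndim = ndim
        self.kernel = kernel
        self.in_ch = in_ch
        self.out_ch = out_ch
        fan_in = in_ch * kernel**ndim
        std = np.sqrt(2.0 / fan_in)
        self.w = Param(rng.normal(0.0, std, size=(kernel,) * ndim + (in_ch, out_ch)))
        self.b = Param(np.zeros(out_ch))
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        nd, k = self.ndim, self.kernel
        pad = k // 2
        spatial = x.shape[1:-1]
        xp = np.pad(x, ((0, 0),) + ((pad, pad),) * nd + ((0, 0),))
        m = x.shape[0] * int(np.prod(spatial))
        out = np.zeros((m, self.out_ch), dtype=np.float32)
        for off in _iterproduct(range(k), repeat=nd):
            xsl = xp[(slice(None),) + _spatial_slices(off, spatial) + (slice(None),)]
            out += np.ascontiguousarray(xsl).reshape(m, self.in_ch) @ self.w.value[off]
        out += self.b.value
        if train:
            self._cache = (xp, spatial)
        return out.reshape(x.shape[:-1] + (self.out_ch,))

    def backward(self, dout):
        xp, spatial = self._cache
        nd, k = self.ndim, self.kernel
        b = dout.shape[0]
        m = b * int(np.prod(spatial))
        dflat = np.ascontiguousarray(dout).reshape(m, self.out_ch)
        self.b.grad += dflat.sum(axis=0)
        dxp = np.zeros_like(xp)
        for off in _iterproduct(range(k), repeat=nd):
            idx = (slice(None),) + _spatial_slices(off, spatial) + (slice(None),)
            xsl = np.ascontiguousarray(xp[idx]).reshape(m, self.in_ch)
            self.w.grad[off] += xsl.T @ dflat
            dxp[idx] += (dflat @ self.w.value[off].T).reshape((b,) + spatial + (self.in_ch,))
        pad = k // 2
        if pad == 0:
            return dxp
        core = (slice(None),) + tuple(slice(pad, -pad) for _ in range(nd)) + (slice(None),)
        return dxp[core]


class BatchNorm(Layer):
    """Per-channel batch normalization over batch and spatial axes."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(np.float32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if train:
            self._cache = (xhat, inv_std, axes)
        return (self.gamma.value * xhat + self.beta.value).astype(np.float32)

    def backward(self, dout):
        xhat, inv_std, axes = self._cache
        n = dout.size // dout.shape[-1]
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        g = self.gamma.value * inv_std
        dx = (g / n) * (
            n * dout
            - dout.sum(axis=axes, keepdims=True)
            - xhat * (dout * xhat).sum(axis=axes, keepdims=True)
        )
        return dx.astype(np.float32)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=False):
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout):
        return dout * self._mask


class MaxPool2(Layer):
    """2x max pooling along every spatial axis (spatial sizes must be even)."""

    def __init__(self, ndim: int):
        self.ndim = ndim
        self._cache = None

    def forward(self, x, train=False):
        nd = self.ndim
        spatial = x.shape[1:-1]
        if any(s % 2 for s in spatial):
            raise ValueError(f"spatial shape {spatial} not divisible by 2")
        b, c = x.shape[0], x.shape[-1]
        half = tuple(s // 2 for s in spatial)
        shape = (b,) + sum(((s, 2) for s in half), ()) + (c,)
        xr = x.reshape(shape)
        # move the window axes (every second spatial axis) to the end
        win_axes = tuple(2 + 2 * i for i in range(nd))
        keep_axes = (0,) + tuple(1 + 2 * i for i in range(nd)) + (xr.ndim - 1,)
        xt = xr.transpose(keep_axes + win_axes)
        windows = xt.reshape((b,) + half + (c, 2**nd))
        idx = windows.argmax(axis=-1)
        out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape, keep_axes, win_axes, shape)
        return np.ascontiguousarray(out)

    def backward(self, dout):
        idx, xshape, keep_axes, win_axes, rshape = self._cache
        nd = self.ndim
        b, c = xshape[0], xshape[-1]
        half = tuple(s // 2 for s in xshape[1:-1])
        dwin = np.zeros((b,) + half + (c, 2**nd), dtype=np.float32)
        np.put_along_axis(dwin, idx[..., None], dout[..., None], axis=-1)
        dxt = dwin.reshape((b,) + half + (c,) + (2,) * nd)
        inv = np.argsort(keep_axes + win_axes)
        return dxt.transpose(inv).reshape(xshape)


class UpConv2(Layer):
    """2x transposed convolution (kernel 2, stride 2) along every spatial axis."""

    def __init__(self, in_ch: int, out_ch: int, ndim: int, rng: np.random.Generator):
        self.ndim = ndim
        self.in_ch = in_ch
        self.out_ch = out_ch
        std = np.sqrt(2.0 / in_ch)
        self.w = Param(rng.normal(0.0, std, size=(2,) * ndim + (in_ch, out_ch)))
        self.b = Param(np.zeros(out_ch))
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        nd = self.ndim
        spatial = x.shape[1:-1]
        b = x.shape[0]
        m = b * int(np.prod(spatial))
        xflat = np.ascontiguousarray(x).reshape(m, self.in_ch)
        out = np.empty((b,) + tuple(2 * s for s in spatial) + (self.out_ch,), dtype=np.float32)
        for off in _iterproduct(range(2), repeat=nd):
            idx = (slice(None),) + tuple(slice(o, None, 2) for o in off) + (slice(None),)
            out[idx] = (xflat @ self.w.value[off]).reshape((b,) + spatial + (self.out_ch,))
        out += self.b.value
        if train:
            self._cache = (xflat, x.shape)
        return out

    def backward(self, dout):
        xflat, xshape = self._cache
        nd = self.ndim
        b = xshape[0]
        spatial = xshape[1:-1]
        m = b * int(np.prod(spatial))
        self.b.grad += dout.sum(axis=tuple(range(dout.ndim - 1)))
        dx = np.zeros((m, self.in_ch), dtype=np.float32)
        for off in _iterproduct(range(2), repeat=nd):
            idx = (slice(None),) + tuple(slice(o, None, 2) for o in off) + (slice(None),)
            dsl = np.ascontiguousarray(dout[idx]).reshape(m, self.out_ch)
            self.w.grad[off] += xflat.T @ dsl
            dx += dsl @ self.w.value[off].T
        return dx.reshape(xshape)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad**2
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
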