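"""Minimal NumPy neural-network core: conv/pool/affine layers with backprop.

Layers are deliberately functional about activations: ``forward`` returns
``(output, cache)`` and ``backward(grad, cache)`` returns the input gradient
while accumulating parameter gradients in place.  Keeping the cache explicit
lets a training step run several forward passes (one per augmented view)
before any backward pass.  Activations are single images ``(C, H, W)``;
batches are handled by the caller accumulating gradients.

Everything is plain float64 NumPy, so runs are bit-reproducible for a fixed
seed on one machine.
"""

from __future__ import annotations

import math
from typing import Any

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = [
    "Conv2D",
    "ReLU",
    "Tanh",
    "AdaptiveAvgPool2D",
    "GlobalAvgPool",
    "Linear",
    "CoordAppend",
    "Sequential",
    "SGD",
    "softmax",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(C, H, W) -> (Ho*Wo, C*k*k) patch matrix (view-based, then copied)."""
    c, h, w = x.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    sc, sh, sw = x.strides
    patches = as_strided(
        x,
        shape=(c, ho, wo, k, k),
        strides=(sc, sh * stride, sw * stride, sh, sw),
    )
    return patches.transpose(1, 2, 0, 3, 4).reshape(ho * wo, c * k * k).copy()


class Conv2D:
    """2-D convolution (cross-correlation) with zero padding, He-initialized."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        ksize: int = 3,
        stride: int = 1,
        pad: int = 0,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng()
        fan_in = in_channels * ksize * ksize
        self.w = rng.normal(0.0, math.sqrt(2.0 / fan_in), (out_channels, in_channels, ksize, ksize))
        self.b = np.zeros(out_channels)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.ksize, self.stride, self.pad = ksize, stride, pad

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, Any]:
        if self.pad:
            x = np.pad(x, ((0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        cols = _im2col(x, self.ksize, self.stride)
        cout = self.w.shape[0]
        wmat = self.w.reshape(cout, -1)
        y = cols @ wmat.T + self.b
        h = (x.shape[1] - self.ksize) // self.stride + 1
        w_ = (x.shape[2] - self.ksize) // self.stride + 1
        out = y.T.reshape(cout, h, w_)
        return out, (cols, x.shape)

    def backward(self, grad: np.ndarray, cache: Any) -> np.ndarray:
        cols, padded_shape = cache
        cout, h, w_ = grad.shape
        gy = grad.reshape(cout, -1).T  # (Ho*Wo, Cout)
        wmat = self.w.reshape(cout, -1)
        self.gw += (gy.T @ cols).reshape(self.w.shape)
        self.gb += gy.sum(axis=0)
        gcols = gy @ wmat  # (Ho*Wo, C*k*k)
        c = padded_shape[0]
        gx = np.zeros(padded_shape)
        gpatch = gcols.reshape(h, w_, c, self.ksize, self.ksize).transpose(2, 0, 1, 3, 4)
        k, s = self.ksize, self.stride
        for di in range(k):
            for dj in range(k):
                gx[:, di : di + s * h : s, dj : dj + s * w_ : s] += gpatch[:, :, :, di, dj]
        if self.pad:
            gx = gx[:, self.pad : -self.pad, self.pad : -self.pad]
        return gx

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(self.w, self.gw), (self.b, self.gb)]


class ReLU:
    def forward(self, x: np.ndarray) -> tuple[np.ndarray, Any]:
        mask = x > 0
        return x * mask, mask

    def backward(self, grad: np.ndarray, cache: Any) -> np.ndarray:
        return grad * cache

    def params(self) -> list:
        return []


class LeakyReLU:
    """max(x, slope*x); the nonzero slope keeps dead units recoverable."""

    def __init__(self, slope: float = 0.1) -> None:
        self.slope = slope

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, Any]:
        mask = x > 0
        return np.where(mask, x, self.slope * x), mask

    def backward(self, grad: np.ndarray, cache: Any) -> np.ndarray:
        return np.where(cache, grad, self.slope * grad)

    def params(self) -> list:
        return []


class Tanh:
    def forward(self, x: np.ndarray) -> tuple[np.ndarray, Any]:
        y = np.tanh(x)
        return y, y

    def backward(self, grad: np.ndarray, cache: Any) -> np.ndarray:
        return grad * (1.0 - cache**2)

    def params(self) -> list:
        return []


def _pool_bins(size: int, n_out: int) -> list[tuple[int, int]]:
    """Adaptive-pooling bin edges: bin p covers [floor(p*S/n), ceil((p+1)*S/n))."""
    return [
        (math.floor(p * size / n_out), math.ceil((p + 1) * size / n_out))
        for p in range(n_out)
    ]


class AdaptiveAvgPool2D:
    """Average-pool a (C, H, W) map onto a fixed (C, n, n) grid."""

    def __init__(self, n_out: int) -> None:
        self.n_out = n_out

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, Any]:
        c, h, w = x.shape
        n = self.n_out
        if h < n or w < n:
            raise ValueError(f"feature map {h}x{w} smaller than pool grid {n}x{n}")
        rb = _pool_bins(h, n)
        cb = _pool_bins(w, n)
        y = np.empty((c, n, n))
        for a, (r0, r1) in enumerate(rb):
            for b, (c0, c1) in enumerate(cb):
                y[:, a, b] = x[:, r0:r1, c0:c1].mean(axis=(1, 2))
        return y, (x.shape, rb, cb)

    def backward(self, grad: np.ndarray, cache: Any) -> np.ndarray:
        shape, rb, cb = cache
        gx = np.zeros(shape)
        for a, (r0, r1) in enumerate(rb):
            for b, (c0, c1) in enumerate(cb):
                area = (r1 - r0) * (c1 - c0)
                gx[:, r0:r1, c0:c1] += grad[:, a, b][:, None, None] / area
        return gx

    def params(self) -> list:
        return []


class GlobalAvgPool:
    def forward(self, x: np.ndarray) -> tuple[np.ndarray, Any]:
        return x.mean(axis=(1, 2)), x.shape

    def backward(self, grad: np.ndarray, cache: Any) -> np.ndarray:
        c, h, w = cache
        return np.broadcast_to(grad[:, None, None], (c, h, w)) / (h * w)

    def params(self) -> list:
        return []


class Linear:
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng()
        self.w = rng.normal(0.0, math.sqrt(1.0 / in_features), (out_features, in_features))
        self.b = np.zeros(out_features)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, Any]:
        return self.w @ x + self.b, x

    def backward(self, grad: np.ndarray, cache: Any) -> np.ndarray:
        self.gw += np.outer(grad, cache)
        self.gb += grad
        return self.w.T @ grad

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(self.w, self.gw), (self.b, self.gb)]


class CoordAppend:
    """Append two fixed coordinate channels (x rightward, y upward, in [-1, 1]).

    A per-cell linear head downstream can then represent positional regression
    targets directly; the channels carry no parameters and their gradient is
    discarded.
    """

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, Any]:
        c, h, w = x.shape
        xs = np.linspace(-1.0, 1.0, w) if w > 1 else np.zeros(1)
        ys = np.linspace(1.0, -1.0, h) if h > 1 else np.zeros(1)
        xx = np.broadcast_to(xs[None, :], (h, w))
        yy = np.broadcast_to(ys[:, None], (h, w))
        return np.concatenate([x, xx[None], yy[None]], axis=0), c

    def backward(self, grad: np.ndarray, cache: Any) -> np.ndarray:
        return grad[:cache]

    def params(self) -> list:
        return []


class Sequential:
    def __init__(self, *layers: Any) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list]:
        caches = []
        for layer in self.layers:
            x, cache = layer.forward(x)
            caches.append(cache)
        return x, caches

    def backward(self, grad: np.ndarray, caches: list) -> np.ndarray:
        for layer, cache in zip(reversed(self.layers), reversed(caches)):
            grad = layer.backward(grad, cache)
        return grad

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [p for layer in self.layers for p in layer.params()]


class SGD:
    """Stochastic gradient descent with classical momentum and norm clipping.

    ``clip_norm`` bounds the global gradient norm (over all managed
    parameters) before each step, which keeps the combined multi-view
    objective stable without touching the loss definition.
    """

    def __init__(
        self,
        params: list[tuple[np.ndarray, np.ndarray]],
        lr: float,
        momentum: float = 0.0,
        clip_norm: float | None = None,
    ) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.param_pairs = params
        self.lr = lr
        self.momentum = momentum
        self.clip_norm = clip_norm
        self.velocity = [np.zeros_like(w) for w, _ in params]

    def zero_grad(self) -> None:
        for _, g in self.param_pairs:
            g[...] = 0.0

    def scale_grad(self, factor: float) -> None:
        for _, g in self.param_pairs:
            g *= factor

    def step(self) -> None:
        if self.clip_norm is not None:
            total = math.sqrt(sum(float((g**2).sum()) for _, g in self.param_pairs))
            if total > self.clip_norm:
                self.scale_grad(self.clip_norm / total)
        for (w, g), v in zip(self.param_pairs, self.velocity):
            if self.momentum:
                v *= self.momentum
                v += g
                w -= self.lr * v
            else:
                w -= self.lr * g
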