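"""Minimal NHWC convolutional layers with manual backpropagation.

All layers operate on arrays of shape ``(N, H, W, C)``. Each layer caches
what its backward pass needs only when ``train=True`` is passed to
``forward``, so inference runs with bounded memory. Parameters and their
gradients are exposed through ``params()`` / ``grads()`` dictionaries with
matching keys, which is the contract the optimizer relies on.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
]


class Layer:
    """Base class: parameter-free layers inherit the empty dicts."""

    def params(self) -> dict:
        return {}

    def grads(self) -> dict:
        return {}

    def state(self) -> dict:
        """Non-trainable buffers (e.g. batch-norm running stats)."""
        return {}


class Conv2d(Layer):
    """k x k same-padded convolution (k odd), stride 1.

    Computed as a sum of k*k shifted 1x1 matmuls on views of the padded
    input, which beats an im2col gather by a wide margin in numpy.
    """

    def __init__(self, c_in: int, c_out: int, ksize: int = 3, *,
                 rng: np.random.Generator | None = None,
                 dtype=np.float32) -> None:
        if ksize % 2 == 0:
            raise ValueError("ksize must be odd")
        if rng is None:
            rng = np.random.default_rng(0)
        self.c_in, self.c_out, self.ksize = c_in, c_out, ksize
        fan_in = c_in * ksize * ksize
        # He initialization: conv is always followed by ReLU in this package
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            (ksize, ksize, c_in, c_out)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._xp = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, _ = x.shape
        k = self.ksize
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        y = np.zeros((n, h, w, self.c_out), dtype=x.dtype)
        for a in range(k):
            for b in range(k):
                y += xp[:, a:a + h, b:b + w, :] @ self.w[a, b]
        y += self.b
        if train:
            self._xp = xp
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, _ = dy.shape
        k = self.ksize
        p = k // 2
        xp = self._xp
        gw = np.empty_like(self.w)
        for a in range(k):
            for b in range(k):
                gw[a, b] = np.tensordot(xp[:, a:a + h, b:b + w, :], dy,
                                        axes=([0, 1, 2], [0, 1, 2]))
        self.gw = gw
        self.gb = dy.sum(axis=(0, 1, 2))
        dyp = np.pad(dy, ((0, 0), (p, p), (p, p), (0, 0))) if p else dy
        dx = np.zeros((n, h, w, self.c_in), dtype=dy.dtype)
        for a in range(k):
            for b in range(k):
                dx += dyp[:, a:a + h, b:b + w, :] \
                    @ self.w[k - 1 - a, k - 1 - b].T
        self._xp = None
        return dx

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.gw, "b": self.gb}


class ConvTranspose2d(Layer):
    """2x2 transposed convolution with stride 2 (exact 2x upsampling)."""

    def __init__(self, c_in: int, c_out: int, *,
                 rng: np.random.Generator | None = None,
                 dtype=np.float32) -> None:
        if rng is None:
            rng = np.random.default_rng(0)
        self.c_in, self.c_out = c_in, c_out
        self.w = rng.normal(0.0, np.sqrt(2.0 / c_in),
                            (c_in, c_out, 2, 2)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._x = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, _ = x.shape
        y6 = np.tensordot(x, self.w, axes=([3], [0]))  # (N,H,W,c_out,2,2)
        y = np.ascontiguousarray(y6.transpose(0, 1, 4, 2, 5, 3)).reshape(
            n, 2 * h, 2 * w, self.c_out)
        y += self.b
        if train:
            self._x = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h2, w2, _ = dy.shape
        h, w = h2 // 2, w2 // 2
        dyb = dy.reshape(n, h, 2, w, 2, self.c_out).transpose(0, 1, 3, 5, 2, 4)
        self.gw = np.tensordot(self._x, dyb, axes=([0, 1, 2], [0, 1, 2]))
        self.gb = dy.sum(axis=(0, 1, 2))
        dx = np.tensordot(dyb, self.w, axes=([3, 4, 5], [1, 2, 3]))
        self._x = None
        return np.ascontiguousarray(dx)

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.gw, "b": self.gb}


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, c: int, *, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32) -> None:
        self.c = c
        self.momentum = momentum
        self.eps = eps
        self.gamma = np.ones(c, dtype=dtype)
        self.beta = np.zeros(c, dtype=dtype)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self._xhat = None
        self._istd = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(
                self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(
                self.running_var.dtype)
        else:
            mu = self.running_mean
            var = self.running_var
        istd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * istd
        if train:
            self._xhat = xhat
            self._istd = istd
        return self.gamma * xhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, istd = self._xhat, self._istd
        m = dy.shape[0] * dy.shape[1] * dy.shape[2]
        self.ggamma = (dy * xhat).sum(axis=(0, 1, 2))
        self.gbeta = dy.sum(axis=(0, 1, 2))
        dxhat = dy * self.gamma
        dx = (istd / m) * (m * dxhat
                           - dxhat.sum(axis=(0, 1, 2))
                           - xhat * (dxhat * xhat).sum(axis=(0, 1, 2)))
        self._xhat = None
        self._istd = None
        return dx.astype(dy.dtype, copy=False)

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.ggamma, "beta": self.gbeta}

    def state(self):
        return {"running_mean": self.running_mean,
                "running_var": self.running_var}


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2d(Layer):
    """2x2 max pooling with stride 2. Input H and W must be even."""

    def __init__(self) -> None:
        self._idx = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2d needs even spatial dims, got {h}x{w}")
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        xr = np.ascontiguousarray(xr).reshape(n, h // 2, w // 2, c, 4)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._inshape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._inshape
        dxr = np.zeros((n, h // 2, w // 2, c, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(n, h // 2, w // 2, c, 2, 2).transpose(
            0, 1, 4, 2, 5, 3)
        dx = np.ascontiguousarray(dxr).reshape(n, h, w, c)
        self._idx = None
        return dx
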