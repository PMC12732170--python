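"""Minimal trainable neural-network layers in numpy.

The classifier at the heart of this package (a VGG16-style convolutional
feature extractor followed by tokenized MLP-Mixer blocks) is implemented on
top of these layers.  Each layer exposes ``forward(x)`` / ``backward(dout)``
with explicit analytic gradients, accumulated into ``grads`` so an optimizer
can walk the parameter tree.  Arrays are channels-last: images are
``(N, H, W, C)``, token matrices are ``(N, S, C)``.

Gradients are exact (verified against central finite differences in the test
suite), and every layer is deterministic, so fixed seeds give bit-identical
training runs on a given platform.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

__all__ = [
    "Layer",
    "Dense",
    "Conv2D",
    "MaxPool2",
    "ReLU",
    "GELU",
    "LayerNorm",
    "gelu",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(x: np.ndarray) -> np.ndarray:
    """Exact (erf-based) Gaussian Error Linear Unit; gelu(0) == 0."""
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    phi = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
    cdf = 0.5 * (1.0 + erf(x / _SQRT2))
    return cdf + x * phi


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean categorical cross-entropy.

    Returns ``(loss, dlogits)`` where ``y`` holds integer class indices of
    shape ``(N,)`` and ``dlogits`` is the gradient of the mean loss.
    """
    n = logits.shape[0]
    p = softmax(logits, axis=-1)
    eps = np.finfo(p.dtype).tiny
    loss = -np.mean(np.log(p[np.arange(n), y] + eps))
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


class Layer:
    """Base layer: parameter/gradient dicts plus a training-mode flag."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.training = True

    def zero_grads(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - abstract
        raise NotImplementedError


class Dense(Layer):
    """Affine map on the last axis, weights shared over all leading axes.

    This is exactly the "fully connected layer with shared weights" used both
    for the token projection and inside the mixer MLPs: an input of shape
    ``(..., d_in)`` is mapped row-wise to ``(..., d_out)``.
    """

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None,
                 init: str = "glorot", dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if init == "he":
            scale = np.sqrt(2.0 / d_in)
        elif init == "glorot":
            scale = np.sqrt(2.0 / (d_in + d_out))
        elif init == "zeros":
            scale = 0.0
        else:
            raise ValueError(f"unknown init {init!r}")
        self.params["W"] = (scale * rng.standard_normal((d_in, d_out))).astype(dtype)
        self.params["b"] = np.zeros(d_out, dtype=dtype)
        self.zero_grads()

    def forward(self, x):
        self._x = x if self.training else None
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        d2 = dout.reshape(-1, dout.shape[-1])
        self.grads["W"] += x2.T @ d2
        self.grads["b"] += d2.sum(axis=0)
        return dout @ self.params["W"].T


class Conv2D(Layer):
    """3x3 (by default) same-padding convolution, stride 1, channels last."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (k * k * c_in))  # He init for the ReLU stack
        self.k = k
        self.pad = k // 2
        self.c_in, self.c_out = c_in, c_out
        self.params["W"] = (scale * rng.standard_normal((k * k * c_in, c_out))).astype(dtype)
        self.params["b"] = np.zeros(c_out, dtype=dtype)
        self.zero_grads()

    def _im2col(self, xp, n, h, w):
        v = sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
        # (N, H, W, C, k, k) -> (N*H*W, k*k*C) in (row, col, channel) order
        return np.ascontiguousarray(v.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n * h * w, self.k * self.k * self.c_in)

    def forward(self, x):
        n, h, w, _ = x.shape
        xp = np.pad(x, ((0, 0), (self.pad, self.pad), (self.pad, self.pad), (0, 0)))
        cols = self._im2col(xp, n, h, w)
        out = (cols @ self.params["W"] + self.params["b"]).reshape(n, h, w, self.c_out)
        if self.training:
            self._cols, self._xshape = cols, x.shape
        else:
            self._cols = None
        return out

    def backward(self, dout):
        n, h, w, _ = self._xshape
        d2 = dout.reshape(-1, self.c_out)
        self.grads["W"] += self._cols.T @ d2
        self.grads["b"] += d2.sum(axis=0)
        dcols = (d2 @ self.params["W"].T).reshape(n, h, w, self.k, self.k, self.c_in)
        dxp = np.zeros((n, h + 2 * self.pad, w + 2 * self.pad, self.c_in), dtype=dout.dtype)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, i, j, :]
        p = self.pad
        return dxp[:, p:p + h, p:p + w, :]


class MaxPool2(Layer):
    """2x2 max pooling with stride 2 and floor semantics (odd trailing
    rows/columns are dropped, matching VGG's dimension arithmetic)."""

    def forward(self, x):
        n, h, w, c = x.shape
        ho, wo = h // 2, w // 2
        xr = x[:, :2 * ho, :2 * wo, :].reshape(n, ho, 2, wo, 2, c)
        xw = np.ascontiguousarray(xr.transpose(0, 1, 3, 5, 2, 4)).reshape(n, ho, wo, c, 4)
        idx = xw.argmax(axis=-1)
        out = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]
        if self.training:
            self._idx, self._xshape = idx, x.shape
        return out

    def backward(self, dout):
        n, h, w, c = self._xshape
        ho, wo = h // 2, w // 2
        dxw = np.zeros((n, ho, wo, c, 4), dtype=dout.dtype)
        np.put_along_axis(dxw, self._idx[..., None], dout[..., None], axis=-1)
        dxr = dxw.reshape(n, ho, wo, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        dx = np.zeros((n, h, w, c), dtype=dout.dtype)
        dx[:, :2 * ho, :2 * wo, :] = dxr.reshape(n, 2 * ho, 2 * wo, c)
        return dx


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class GELU(Layer):
    def forward(self, x):
        self._x = x
        return gelu(x)

    def backward(self, dout):
        return dout * gelu_grad(self._x)


class LayerNorm(Layer):
    """Layer normalization over the last axis with learnable scale/shift."""

    def __init__(self, dim: int, eps: float = 1e-6, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.params["gamma"] = np.ones(dim, dtype=dtype)
        self.params["beta"] = np.zeros(dim, dtype=dtype)
        self.zero_grads()

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._xhat, self._inv = xhat, inv
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout):
        xhat, inv = self._xhat, self._inv
        g = self.params["gamma"]
        self.grads["gamma"] += np.sum(dout * xhat, axis=tuple(range(dout.ndim - 1)))
        self.grads["beta"] += np.sum(dout, axis=tuple(range(dout.ndim - 1)))
        dxhat = dout * g
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)


class Adam:
    """Adam over the parameters of a list of layers."""

    def __init__(self, layers, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self._v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def zero_grads(self):
        for l in self.layers:
            l.zero_grads()

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for l, m, v in zip(self.layers, self._m, self._v):
            for k, p in l.params.items():
                g = l.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                p -= self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)
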