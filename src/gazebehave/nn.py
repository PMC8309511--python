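"""Minimal CPU neural-network layer stack (numpy, float32).

Provides exactly what the stare/move raster classifiers need: im2col-based
2-D convolution, 2x2 max pooling, dense layers, ReLU/sigmoid activations,
softmax cross-entropy, and Adam.  Training is deterministic for a fixed
seed on one machine (all randomness flows through one Generator and BLAS
matmuls are used in a fixed order).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "MaxPool2D",
    "Dense",
    "ReLU",
    "Sigmoid",
    "Flatten",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Layer:
    """Base layer: forward caches what backward needs; params/grads in lists."""

    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """2-D convolution (cross-correlation), NCHW, via im2col + matmul."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        pad: int = 0,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.pad = kernel, stride, pad
        self.in_ch, self.out_ch = in_ch, out_ch
        fan_in = in_ch * kernel * kernel
        self.W = _he_init(rng, (fan_in, out_ch), fan_in)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _cols(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        v = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        v = v[:, :, ::s, ::s, :, :]  # (n, c, ho, wo, k, k)
        cols = v.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        return np.ascontiguousarray(cols), (n, c, h, w, ho, wo)

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, meta = self._cols(x)
        self._cols_cache, self._meta = cols, meta
        n, c, h, w, ho, wo = meta
        out = cols @ self.W + self.b
        return out.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w, ho, wo = self._meta
        k, s, p = self.k, self.stride, self.pad
        d = dout.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.out_ch)
        self.grads[0][...] = self._cols_cache.T @ d
        self.grads[1][...] = d.sum(axis=0)
        dcols = (d @ self.W.T).reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += dcols[
                    :, :, ki, kj, :, :
                ]
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2 (odd trailing rows/cols are dropped)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        x = x[:, :, : h2 * 2, : w2 * 2]
        v = x.reshape(n, c, h2, 2, w2, 2)
        out = v.max(axis=(3, 5))
        self._mask = v == out[:, :, :, None, :, None]
        self._shape = (n, c, h, w)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        h2, w2 = h // 2, w // 2
        dv = self._mask * dout[:, :, :, None, :, None]
        dx = np.zeros((n, c, h, w), dtype=np.float32)
        dx[:, :, : h2 * 2, : w2 * 2] = dv.reshape(n, c, h2 * 2, w2 * 2)
        return dx


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = _he_init(rng, (n_in, n_out), n_in)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._y * (1.0 - self._y)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and the gradient wrt logits."""
    p = softmax(logits.astype(np.float64))
    n = len(y)
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    grad = p
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(np.float32)


class Sequential:
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def predict_proba(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        out = []
        for lo in range(0, len(x), batch):
            out.append(softmax(self.forward(x[lo : lo + batch])))
        return np.concatenate(out, axis=0)

    def predict(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        return self.predict_proba(x, batch).argmax(axis=1)

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def load_state(self, state: Sequence[np.ndarray]) -> None:
        for p, s in zip(self.params, state):
            p[...] = s


class Adam:
    def __init__(self, params: Sequence[np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
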