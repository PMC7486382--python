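"""Minimal NumPy neural-network layers with manual backpropagation.

Only what the gaze network needs: 2-D convolution with TensorFlow-style
"same" padding, 2x2 average pooling, dense layers, ReLU, and an Adam
optimizer.  Arrays are NHWC ``float32``; convolution is evaluated as a
single im2col matrix product per layer, which is the fastest arrangement
for these small feature maps under plain NumPy.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = ["Conv2d", "AvgPool2d", "ReLU", "Dense", "Flatten", "Sequential", "Adam"]


class Layer:
    """Base class: forward caches whatever backward needs."""

    def params(self) -> List[np.ndarray]:
        return []

    def grads(self) -> List[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


def _same_pad(size: int, k: int, s: int) -> tuple:
    out = -(-size // s)  # ceil division
    total = max((out - 1) * s + k - size, 0)
    return out, total // 2, total - total // 2


class Conv2d(Layer):
    """k x k convolution, stride ``s``, "same" padding, He-initialised."""

    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int, rng: np.random.Generator,
                 compute_input_grad: bool = True):
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, k, stride
        # the first layer of a network never needs d(loss)/d(input)
        self.compute_input_grad = compute_input_grad
        fan_in = k * k * in_ch
        self.W = (rng.standard_normal((fan_in, out_ch)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, H, W, C = x.shape
        k, s = self.k, self.stride
        oh, pt, pb = _same_pad(H, k, s)
        ow, pl, pr = _same_pad(W, k, s)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        sb, sh, sw, sc = xp.strides
        view = as_strided(
            xp,
            shape=(B, oh, ow, k, k, C),
            strides=(sb, s * sh, s * sw, sh, sw, sc),
        )
        cols = np.ascontiguousarray(view).reshape(B * oh * ow, k * k * C)
        out = cols @ self.W + self.b
        self._cache = (cols, (B, H, W, C), (oh, ow, pt, pl))
        return out.reshape(B, oh, ow, self.out_ch)

    def backward(self, g: np.ndarray) -> np.ndarray:
        cols, (B, H, W, C), (oh, ow, pt, pl) = self._cache
        k, s = self.k, self.stride
        gflat = g.reshape(B * oh * ow, self.out_ch)
        self.gW[...] = cols.T @ gflat
        self.gb[...] = gflat.sum(axis=0)
        if not self.compute_input_grad:
            return None
        gcols = (gflat @ self.W.T).reshape(B, oh, ow, k, k, C)
        gxp = np.zeros((B, s * (oh - 1) + k, s * (ow - 1) + k, C), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                gxp[:, i : i + s * oh : s, j : j + s * ow : s, :] += gcols[:, :, :, i, j, :]
        return gxp[:, pt : pt + H, pl : pl + W, :]


class AvgPool2d(Layer):
    """Non-overlapping 2x2 average pooling (even spatial dims assumed)."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, H, W, C = x.shape
        p = self.size
        self._shape = x.shape
        return x.reshape(B, H // p, p, W // p, p, C).mean(axis=(2, 4))

    def backward(self, g: np.ndarray) -> np.ndarray:
        B, H, W, C = self._shape
        p = self.size
        g = g / (p * p)
        return np.broadcast_to(
            g[:, :, None, :, None, :], (B, H // p, p, W // p, p, C)
        ).reshape(B, H, W, C).astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, 0.0).astype(np.float32)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.gW[...] = self._x.T @ g
        self.gb[...] = g.sum(axis=0)
        return (g @ self.W.T).astype(np.float32)


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            g = l.backward(g)
        return g


class Adam:
    """Adam with the standard bias correction; state keyed by parameter order."""

    def __init__(self, params: Sequence[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
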