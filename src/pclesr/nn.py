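"""Minimal CPU convolutional-network engine with reverse-mode gradients.

Purpose-built for small fully-convolutional enhancement networks at
scale factor 1: stride-1 'same' convolutions, ReLU, residual blocks and
an Adam optimiser.  Data is channels-last ``(N, H, W, C)`` float32;
convolutions run as a single im2col GEMM per layer, and the im2col
buffer is reused by the weight-gradient GEMM in the backward pass.

Initialisation is deterministic for a given ``numpy`` Generator.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "ReLU", "Sequential", "ResidualBlock", "Adam"]

DTYPE = np.float32


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """Stride-1 'same' 2-D convolution, odd kernel, zero padding.

    Weights are stored GEMM-ready as ``(k*k*c_in, c_out)``.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 zero_init: bool = False):
        assert kernel % 2 == 1, "odd kernels only"
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * kernel * kernel
        if zero_init:
            self.weight = np.zeros((fan_in, c_out), dtype=DTYPE)
        else:
            # He-normal, fan-in scaled (ReLU networks)
            std = np.sqrt(2.0 / fan_in)
            self.weight = rng.normal(0.0, std, size=(fan_in, c_out)).astype(DTYPE)
        self.bias = np.zeros(c_out, dtype=DTYPE)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def params(self):
        return [self.weight, self.bias]

    def grads(self):
        return [self.dweight, self.dbias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, _ = x.shape
        k, p = self.kernel, (self.kernel - 1) // 2
        if p:
            x = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        # (N, H, W, k, k, C) view -> contiguous (N*H*W, k*k*C)
        win = sliding_window_view(x, (k, k), axis=(1, 2))  # (N, H, W, C, k, k)
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(n * h * w, -1)
        self._cols, self._shape = cols, (n, h, w)
        y = cols @ self.weight + self.bias
        return y.reshape(n, h, w, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w = self._shape
        k, p = self.kernel, (self.kernel - 1) // 2
        dy_flat = dy.reshape(n * h * w, self.c_out)
        self.dbias[...] = dy_flat.sum(axis=0)
        self.dweight[...] = self._cols.T @ dy_flat
        dcols = (dy_flat @ self.weight.T).reshape(n, h, w, k, k, self.c_in)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, self.c_in), dtype=dy.dtype)
        for a in range(k):
            for b in range(k):
                dxp[:, a : a + h, b : b + w, :] += dcols[:, :, :, a, b, :]
        return dxp[:, p : p + h, p : p + w, :] if p else dxp

    @property
    def receptive_growth(self) -> int:
        return self.kernel - 1


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(x.dtype)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(dy.dtype)

    receptive_growth = 0


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy

    @property
    def receptive_growth(self) -> int:
        return sum(l.receptive_growth for l in self.layers)


class ResidualBlock(Layer):
    """conv-ReLU-conv with an identity skip (no batch normalisation)."""

    def __init__(self, width: int, rng: np.random.Generator):
        self.body = Sequential([Conv2d(width, width, 3, rng), ReLU(), Conv2d(width, width, 3, rng)])

    def params(self):
        return self.body.params()

    def grads(self):
        return self.body.grads()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x + self.body.forward(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy + self.body.backward(dy)

    @property
    def receptive_growth(self) -> int:
        return self.body.receptive_growth


class Adam:
    """Adam optimiser over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= (self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)).astype(p.dtype)
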