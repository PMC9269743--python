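"""Minimal numpy neural-network core: 1-D convolutional layers with
backpropagation and an Adam optimizer.

Only the pieces the generator, discriminator and night classifier need are
implemented: dense and 1-D convolution layers ("same" padding, arbitrary
stride), nearest-neighbour upsampling, max pooling, leaky-ReLU / tanh /
sigmoid activations, and binary cross-entropy.  All randomness flows through
an explicit ``numpy.random.Generator`` so models are bit-reproducible under a
fixed seed.  Arrays are ``float64``; sequence tensors are shaped
``(batch, channels, length)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Dense",
    "Conv1D",
    "UpSample1D",
    "MaxPool1D",
    "LeakyReLU",
    "Tanh",
    "Sigmoid",
    "Flatten",
    "Reshape",
    "Sequential",
    "Adam",
    "bce_loss",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("val", "grad")

    def __init__(self, val: np.ndarray):
        self.val = np.asarray(val, dtype=np.float64)
        self.grad = np.zeros_like(self.val)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.W = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        x = np.asarray(x, dtype=self.W.val.dtype)
        self._x = x
        return x @ self.W.val + self.b.val

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.val.T


class Conv1D(Layer):
    """1-D convolution with "same" padding and arbitrary stride.

    Implemented as im2col + matmul so the heavy lifting is a BLAS call;
    the column matrix is cached for the backward pass.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1):
        if kernel < 1 or stride < 1:
            raise ValueError("kernel and stride must be positive")
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, kernel, stride
        scale = np.sqrt(2.0 / (c_in * kernel + c_out))
        self.W = Param(rng.normal(0.0, scale, size=(c_out, c_in, kernel)))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.W, self.b]

    def _pad(self, length: int) -> tuple[int, int, int]:
        l_out = -(-length // self.stride)  # ceil
        pad_total = max((l_out - 1) * self.stride + self.k - length, 0)
        return l_out, pad_total // 2, pad_total - pad_total // 2

    def forward(self, x):
        x = np.asarray(x, dtype=self.W.val.dtype)
        n, c, length = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        l_out, pl, pr = self._pad(length)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        win = win[:, :, :: self.stride]  # (n, c, l_out, k)
        col = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(
            n * l_out, self.c_in * self.k)
        w_mat = self.W.val.reshape(self.c_out, -1)
        y = (col @ w_mat.T).reshape(n, l_out, self.c_out) + self.b.val
        self._cache = (col, n, length, l_out, pl, xp.shape[2])
        return y.transpose(0, 2, 1)

    def backward(self, dy):
        col, n, length, l_out, pl, lp = self._cache
        dy = np.asarray(dy, dtype=self.W.val.dtype)
        dy_t = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(n * l_out, self.c_out)
        w_mat = self.W.val.reshape(self.c_out, -1)
        self.W.grad += (dy_t.T @ col).reshape(self.W.val.shape)
        self.b.grad += dy_t.sum(axis=0)
        dcol = (dy_t @ w_mat).reshape(n, l_out, self.c_in, self.k)
        dxp = np.zeros((n, self.c_in, lp), dtype=self.W.val.dtype)
        for j in range(self.k):  # k is small; each slice update is vectorized
            dxp[:, :, j: j + self.stride * l_out: self.stride] += \
                dcol[:, :, :, j].transpose(0, 2, 1)
        return dxp[:, :, pl: pl + length]


class UpSample1D(Layer):
    """Nearest-neighbour upsampling along the sequence axis."""

    def __init__(self, factor: int):
        self.factor = factor

    def forward(self, x):
        self._shape = x.shape
        return np.repeat(x, self.factor, axis=2)

    def backward(self, dy):
        n, c, length = self._shape
        return dy.reshape(n, c, length, self.factor).sum(axis=3)


class MaxPool1D(Layer):
    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x):
        n, c, length = x.shape
        if length % self.size:
            raise ValueError("sequence length must be divisible by pool size")
        xr = x.reshape(n, c, length // self.size, self.size)
        self._idx = xr.argmax(axis=3)
        self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, dy):
        n, c, length = self._shape
        dxr = np.zeros((n, c, length // self.size, self.size), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=3)
        return dxr.reshape(n, c, length)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy)


class Tanh(Layer):
    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy):
        return dy * (1.0 - self._y ** 2)


class Sigmoid(Layer):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Reshape(Layer):
    """Reshape the per-sample part of the batch, e.g. (n, 3600) -> (n, 50, 72)."""

    def __init__(self, shape: tuple[int, ...]):
        self.shape = shape

    def forward(self, x):
        self._in = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dy):
        return dy.reshape(self._in)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self):
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def astype(self, dtype) -> "Sequential":
        """Cast all parameters (single precision halves the BLAS cost)."""
        for p in self.params():
            p.val = p.val.astype(dtype)
            p.grad = np.zeros_like(p.val)
        return self

    # -- weight (de)serialization -------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.val.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.params()
        if len(weights) != len(params):
            raise ValueError("weight count mismatch")
        for p, w in zip(params, weights):
            if p.val.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p.val = np.array(w, dtype=p.val.dtype)
            p.grad = np.zeros_like(p.val)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.val) for p in params]
        self.v = [np.zeros_like(p.val) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            p.val -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def bce_loss(p: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Binary cross-entropy on probabilities; returns (loss, dL/dp)."""
    y = np.asarray(y, dtype=p.dtype)
    eps = max(1e-7, float(np.finfo(p.dtype).eps) * 10)  # keep 1-eps != 1
    p = np.clip(p, eps, 1.0 - eps)
    loss = float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
    grad = (p - y) / (p * (1.0 - p)) / p.size
    return loss, grad
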