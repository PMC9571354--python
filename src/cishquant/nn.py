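"""Minimal NumPy neural-network layers for the 3-class segmentation U-net.

Convolutions are lowered to GEMM via im2col (float32 throughout), which is
fast enough on one CPU core for the desk-scale training this package does.
Gradients of stride-1 same-padded 3x3 convolutions are themselves 3x3
correlations with the spatially flipped, channel-transposed kernel, so the
backward pass reuses the same im2col/GEMM machinery and never scatters.

Layout is NHWC.  All randomness (initialisation) is injected through a
``numpy.random.Generator`` so training is reproducible bit-for-bit.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Param", "Conv3x3", "Conv1x1", "BatchNorm", "ReLU", "MaxPool2", "Upsample2", "ConvBlock", "Adam", "softmax_cross_entropy"]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N,H,W,C) -> (N*H*W, C*9) patch matrix for a same-padded 3x3 window."""
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (N,H,W,C,3,3)
    return win.reshape(n * h * w, c * 9)


class Conv3x3:
    """Same-padded 3x3 convolution. Weight layout (Cin, 3, 3, Cout)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (9 * c_in))
        self.w = Param(rng.normal(0.0, std, size=(c_in, 3, 3, c_out)).astype(np.float32))
        self.b = Param(np.zeros(c_out, dtype=np.float32))
        self.c_in, self.c_out = c_in, c_out
        self._x_col: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, _ = x.shape
        col = _im2col3(x)
        if train:
            self._x_col, self._shape = col, x.shape
        y = col @ self.w.value.reshape(-1, self.c_out) + self.b.value
        return y.reshape(n, h, w, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, _ = dy.shape
        dy_flat = dy.reshape(-1, self.c_out)
        self.w.grad += (self._x_col.T @ dy_flat).reshape(self.w.value.shape)
        self.b.grad += dy_flat.sum(axis=0)
        # dX = correlation of dY with the flipped, transposed kernel
        w_back = self.w.value[:, ::-1, ::-1, :].transpose(3, 1, 2, 0).reshape(-1, self.c_in)
        dx = _im2col3(dy) @ w_back
        self._x_col = None
        return dx.reshape(n, h, w, self.c_in)


class Conv1x1:
    """Pointwise convolution (the softmax head)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / c_in)
        self.w = Param(rng.normal(0.0, std, size=(c_in, c_out)).astype(np.float32))
        self.b = Param(np.zeros(c_out, dtype=np.float32))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c_in, c_out = self.w.value.shape
        self.w.grad += self._x.reshape(-1, c_in).T @ dy.reshape(-1, c_out)
        self.b.grad += dy.reshape(-1, c_out).sum(axis=0)
        self._x = None
        return dy @ self.w.value.T


class BatchNorm:
    """Per-channel batch normalisation over (N, H, W) with running stats."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(c, dtype=np.float32))
        self.beta = Param(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        x_hat = (x - mean) * inv_std
        if train:
            self._cache = (x_hat, inv_std.astype(np.float32))
        return (self.gamma.value * x_hat + self.beta.value).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_hat, inv_std = self._cache
        m = dy.shape[0] * dy.shape[1] * dy.shape[2]
        self.gamma.grad += (dy * x_hat).sum(axis=(0, 1, 2))
        self.beta.grad += dy.sum(axis=(0, 1, 2))
        dxhat = dy * self.gamma.value
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 1, 2))
            - x_hat * (dxhat * x_hat).mean(axis=(0, 1, 2))
        ) * inv_std
        self._cache = None
        return dx.astype(np.float32)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
            return np.where(self._mask, x, 0.0).astype(np.float32)
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dy, 0.0)
        self._mask = None
        return dx


class MaxPool2:
    """2x2 max pooling; gradient is split evenly among tied maxima."""

    def __init__(self):
        self._cache = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        y = xr.max(axis=(2, 4))
        if train:
            self._cache = (xr, y)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xr, y = self._cache
        mask = xr == y[:, :, None, :, None, :]
        counts = mask.sum(axis=(2, 4), keepdims=True)
        dx = mask * (dy[:, :, None, :, None, :] / counts)
        n, hh, _, ww, _, c = xr.shape
        self._cache = None
        return dx.reshape(n, hh * 2, ww * 2, c).astype(np.float32)


class Upsample2:
    """Nearest-neighbour 2x upsampling; gradient is a 2x2 sum pool."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class ConvBlock:
    """Conv3x3 -> BatchNorm -> ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.conv = Conv3x3(c_in, c_out, rng)
        self.bn = BatchNorm(c_out)
        self.relu = ReLU()

    def params(self) -> list[Param]:
        return self.conv.params() + self.bn.params()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.relu.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.bn.backward(self.relu.backward(dy)))


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean categorical cross-entropy over all pixels.

    Returns (loss, probabilities, gradient w.r.t. logits).  ``labels`` holds
    integer classes of shape (N, H, W).
    """
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=-1, keepdims=True)
    n, h, w, k = probs.shape
    flat = probs.reshape(-1, k)
    idx = labels.reshape(-1)
    loss = float(-np.log(np.maximum(flat[np.arange(idx.size), idx], 1e-12)).mean())
    grad = flat.copy()
    grad[np.arange(idx.size), idx] -= 1.0
    grad /= idx.size
    return loss, probs, grad.reshape(n, h, w, k).astype(np.float32)


class Adam:
    """Adaptive-moment optimiser (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[Param], lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
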