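"""Minimal CPU neural-network engine used by the quality scorer.

Implements exactly the building blocks the scorer architecture needs —
im2col-based 2D convolutions, batch normalization, ReLU, residual addition,
PyTorch-semantics adaptive average pooling, fully connected layers — with
hand-written backward passes and an Adam optimizer (L2 weight decay folded
into the gradient, matching ``torch.optim.Adam``).  Everything is float32
and deterministic given a seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

#: Compute dtype for the whole engine; float64 is used by gradient checks.
DTYPE = np.float32

__all__ = [
    "DTYPE",
    "Param",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Linear",
    "AdaptiveAvgPool2d",
    "Adam",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []


class Conv2d(Layer):
    """2D convolution (cross-correlation) with square kernel and symmetric
    zero padding, computed as im2col + matrix multiply."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None):
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride, self.pad = kernel, stride, pad
        fan_in = c_in * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU trunks
        rng = rng or np.random.default_rng()
        self.weight = Param(rng.normal(0.0, scale, size=(c_out, fan_in)).astype(DTYPE))
        self.bias = Param(np.zeros(c_out, dtype=DTYPE))
        self._cols: np.ndarray | None = None
        self._x_shape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, int, int]:
        n, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        view = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        view = view[:, :, ::s, ::s]                       # (n, c, ho, wo, k, k)
        cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        return np.ascontiguousarray(cols, dtype=DTYPE), ho, wo

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n = x.shape[0]
        cols, ho, wo = self._im2col(x)
        out = cols @ self.weight.value.T + self.bias.value
        if train:
            self._cols, self._x_shape, self._out_hw = cols, x.shape, (ho, wo)
        return out.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, _, ho, wo = dout.shape
        k, s, p = self.kernel, self.stride, self.pad
        dflat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1).reshape(-1, self.c_out))
        self.weight.grad += dflat.T @ self._cols
        self.bias.grad += dflat.sum(axis=0)
        dcols = (dflat @ self.weight.value).reshape(n, ho, wo, self.c_in, k, k)
        _, c, h, w = self._x_shape
        self._cols = None
        if k == s and p == 0 and h == s * ho and w == s * wo:
            # non-overlapping windows: col2im is a pure re-layout
            return np.ascontiguousarray(
                dcols.transpose(0, 3, 1, 4, 2, 5).reshape(n, c, h, w)
            )
        dcols = np.ascontiguousarray(dcols.transpose(0, 3, 1, 2, 4, 5))  # (n,c,ho,wo,k,k)
        dx_pad = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=DTYPE)
        for ki in range(k):
            for kj in range(k):
                dx_pad[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += dcols[:, :, :, :, ki, kj]
        return dx_pad[:, :, p : p + h, p : p + w] if p else dx_pad


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels, dtype=DTYPE))
        self.beta = Param(np.zeros(channels, dtype=DTYPE))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = np.einsum("nchw,nchw->c", x, x, optimize=True) / (
                x.shape[0] * x.shape[2] * x.shape[3]
            ) - mean * mean
            var = np.maximum(var, 0.0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * ivar[None, :, None, None]
        if train:
            self._xhat, self._ivar = xhat, ivar
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, ivar = self._xhat, self._ivar
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dgamma = (dout * xhat).sum(axis=(0, 2, 3))
        dbeta = dout.sum(axis=(0, 2, 3))
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = self.gamma.value[None, :, None, None]
        dx = (g * ivar[None, :, None, None] / m) * (
            m * dout
            - dbeta[None, :, None, None]
            - xhat * dgamma[None, :, None, None]
        )
        self._xhat = None
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / n_in)
        self.weight = Param(rng.normal(0.0, scale, size=(n_out, n_in)).astype(DTYPE))
        self.bias = Param(np.zeros(n_out, dtype=DTYPE))

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.weight.grad += dout.T @ self._x
        self.bias.grad += dout.sum(axis=0)
        dx = dout @ self.weight.value
        self._x = None
        return dx


class AdaptiveAvgPool2d(Layer):
    """Average pooling to a fixed output size with torch's window rule:
    window i spans [floor(i*H/out), ceil((i+1)*H/out)).  Works for inputs
    both larger and smaller than the output (windows overlap/replicate)."""

    def __init__(self, out_size: int):
        self.out_size = out_size

    @staticmethod
    def _windows(size_in: int, size_out: int) -> list[tuple[int, int]]:
        return [
            (int(np.floor(i * size_in / size_out)), int(np.ceil((i + 1) * size_in / size_out)))
            for i in range(size_out)
        ]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        o = self.out_size
        out = np.empty((n, c, o, o), dtype=DTYPE)
        hw = self._windows(h, o)
        ww = self._windows(w, o)
        for i, (hs, he) in enumerate(hw):
            for j, (ws, we) in enumerate(ww):
                out[:, :, i, j] = x[:, :, hs:he, ws:we].mean(axis=(2, 3))
        if train:
            self._in_shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        o = self.out_size
        dx = np.zeros((n, c, h, w), dtype=DTYPE)
        hw = self._windows(h, o)
        ww = self._windows(w, o)
        for i, (hs, he) in enumerate(hw):
            for j, (ws, we) in enumerate(ww):
                dx[:, :, hs:he, ws:we] += dout[:, :, i, j][:, :, None, None] / (
                    (he - hs) * (we - ws)
                )
        return dx


class Adam:
    """Adam with L2 weight decay added to the raw gradient (torch.optim.Adam)."""

    def __init__(self, params: list[Param], lr: float, weight_decay: float = 0.0,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.weight_decay = lr, weight_decay
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
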