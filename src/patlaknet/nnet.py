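"""Minimal NumPy layers for 2-D convolutional image regression.

Self-contained building blocks -- dilated 3x3 convolution, batch
normalization, ReLU, pre-activation residual blocks and Adam -- with
hand-written backward passes.  Convolutions use zero padding chosen so
the spatial shape is preserved for any dilation, and are evaluated as
nine shifted BLAS matrix products (one per kernel tap), which is both
memory-light and fast at the image sizes this package works with.
All activations and parameters are float32.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "BatchNorm2d", "ReLU", "Adam"]


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    training = True

    def parameters(self) -> list:
        return []


class Conv2d(Layer):
    """2-D convolution, kernel 3x3 or 1x1, arbitrary dilation, 'same' padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 dilation: int = 1, rng: np.random.Generator | None = None):
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        if in_channels < 1 or out_channels < 1:
            raise ValueError("channel counts must be >= 1")
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU networks
        self.weight = Parameter(rng.normal(0.0, scale,
                                           (out_channels, in_channels, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_channels))
        self.kernel = kernel
        self.dilation = int(dilation)
        self._cache = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        w = self.weight.value
        n, c, h, wd = x.shape
        if self.kernel == 1:
            out = np.tensordot(x, w[:, :, 0, 0], axes=([1], [1]))  # (N,H,W,O)
            out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
            self._cache = x
        else:
            d = self.dilation
            xp = np.pad(x, ((0, 0), (0, 0), (d, d), (d, d)))
            out = np.zeros((n, w.shape[0], h, wd), dtype=np.float32)
            for i in range(3):
                for j in range(3):
                    patch = xp[:, :, i * d:i * d + h, j * d:j * d + wd]
                    out += np.tensordot(patch, w[:, :, i, j],
                                        axes=([1], [1])).transpose(0, 3, 1, 2)
            self._cache = xp
        return out + self.bias.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        w = self.weight.value
        self.bias.grad += dout.sum(axis=(0, 2, 3))
        if self.kernel == 1:
            x = self._cache
            self.weight.grad[:, :, 0, 0] += np.tensordot(dout, x, axes=([0, 2, 3], [0, 2, 3]))
            dx = np.tensordot(dout, w[:, :, 0, 0], axes=([1], [0])).transpose(0, 3, 1, 2)
            return np.ascontiguousarray(dx)
        d = self.dilation
        xp = self._cache
        n, _, h, wd = dout.shape
        dxp = np.zeros_like(xp)
        for i in range(3):
            for j in range(3):
                patch = xp[:, :, i * d:i * d + h, j * d:j * d + wd]
                self.weight.grad[:, :, i, j] += np.tensordot(
                    dout, patch, axes=([0, 2, 3], [0, 2, 3]))
                dxp[:, :, i * d:i * d + h, j * d:j * d + wd] += np.tensordot(
                    dout, w[:, :, i, j], axes=([1], [0])).transpose(0, 3, 1, 2)
        return np.ascontiguousarray(dxp[:, :, d:d + h, d:d + wd])


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        dxhat = dout * g
        if not self.training:
            return dxhat * inv_std[None, :, None, None]
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (dxhat - s1 / m - xhat * s2 / m) * inv_std[None, :, None, None]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0.0))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, np.float32(0.0))


class Adam:
    """Adam with decoupled, schedulable learning rate and L2 weight decay."""

    def __init__(self, params: list, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self, lr: float, weight_decay: float = 0.0) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if weight_decay:
                g = g + np.float32(weight_decay) * p.value
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= np.float32(lr) * mhat / (np.sqrt(vhat) + self.eps)
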