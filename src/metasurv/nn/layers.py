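"""Minimal NumPy layers with explicit forward/backward passes.

Supports the small convolutional survival networks used in this package:
N-dimensional stride-1 "same" convolution, non-overlapping max pooling,
parametric/plain rectifiers, dense layers, inverted dropout and a sigmoid
output.  Every layer exposes ``params`` / ``grads`` (parallel lists) and a
``param_decay`` flag list marking which parameters receive L2 weight decay
(kernels and dense weights; biases and rectifier slopes are exempt).

All computations are float32; gradients are exact (finite-difference
checked in the test suite).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer", "Conv", "MaxPool", "PReLU", "ReLU", "Dense", "Dropout",
    "Flatten", "Sigmoid",
]


class Layer:
    """Base layer: stateless by default, parameters in ``params``."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []
        self.param_decay: list[bool] = []

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def output_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        """Static shape propagation (per-sample shape, no batch axis)."""
        raise NotImplementedError


class Conv(Layer):
    """Stride-1 N-D convolution with zero "same" padding (odd kernels).

    Weights have shape ``(n_kernels, in_channels, *kernel)``; inputs
    ``(batch, in_channels, *spatial)``.
    """

    def __init__(self, in_channels: int, n_kernels: int, kernel_size: int,
                 ndim: int, rng: np.random.Generator) -> None:
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for same padding")
        self.ndim = ndim
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size ** ndim
        scale = np.sqrt(2.0 / fan_in)
        w = rng.normal(0.0, scale, size=(n_kernels, in_channels) + (kernel_size,) * ndim)
        b = np.zeros(n_kernels)
        self.params = [w.astype(np.float32), b.astype(np.float32)]
        self.grads = [np.zeros_like(p) for p in self.params]
        self.param_decay = [True, False]

    def _pad(self, x: np.ndarray) -> np.ndarray:
        p = self.kernel_size // 2
        pad = [(0, 0), (0, 0)] + [(p, p)] * self.ndim
        return np.pad(x, pad)

    def forward(self, x, training=False, rng=None):
        w, b = self.params
        self._xp = self._pad(np.ascontiguousarray(x))
        spatial_axes = tuple(range(2, 2 + self.ndim))
        win = sliding_window_view(self._xp, (self.kernel_size,) * self.ndim,
                                  axis=spatial_axes)
        # win: (N, C, *spatial, *k); contract channels + kernel with w
        axes_win = (1,) + tuple(range(2 + self.ndim, 2 + 2 * self.ndim))
        axes_w = tuple(range(1, 2 + self.ndim))
        out = np.tensordot(win, w, axes=(axes_win, axes_w))
        out = np.moveaxis(out, -1, 1)  # (N, F, *spatial)
        out += b.reshape((1, -1) + (1,) * self.ndim)
        self._out_spatial = out.shape[2:]
        return np.ascontiguousarray(out)

    def backward(self, dy):
        w, _ = self.params
        spatial_axes = tuple(range(2, 2 + self.ndim))
        win = sliding_window_view(self._xp, (self.kernel_size,) * self.ndim,
                                  axis=spatial_axes)
        sum_axes = (0,) + spatial_axes
        # grad_w[f, c, *k] = sum over batch+spatial of dy[n,f,*s] * win[n,c,*s,*k]
        gw = np.tensordot(dy, win, axes=(sum_axes, sum_axes))
        self.grads[0][...] = gw
        self.grads[1][...] = dy.sum(axis=sum_axes)

        dxp = np.zeros_like(self._xp)
        sp = self._out_spatial
        for offset in np.ndindex(*(self.kernel_size,) * self.ndim):
            # dxp[:, c, o : o + sp] += dy[:, f] * w[f, c, offset]
            contrib = np.tensordot(dy, w[(slice(None), slice(None)) + offset],
                                   axes=([1], [0]))  # (N, *spatial, C)
            contrib = np.moveaxis(contrib, -1, 1)
            region = (slice(None), slice(None)) + tuple(
                slice(o, o + s) for o, s in zip(offset, sp))
            dxp[region] += contrib
        p = self.kernel_size // 2
        core = (slice(None), slice(None)) + tuple(slice(p, -p) for _ in range(self.ndim))
        del self._xp
        return dxp[core]

    def output_shape(self, in_shape):
        return (self.params[0].shape[0],) + in_shape[1:]


class MaxPool(Layer):
    """Non-overlapping max pooling (pool size == stride)."""

    def __init__(self, pool_size: int, ndim: int) -> None:
        super().__init__()
        self.pool = pool_size
        self.ndim = ndim

    def _blocked(self, x: np.ndarray) -> np.ndarray:
        n, c = x.shape[:2]
        p = self.pool
        out_sp = tuple(s // p for s in x.shape[2:])
        shape = (n, c) + sum(((o, p) for o in out_sp), ())
        xr = x.reshape(shape)
        # move the p-axes to the end
        order = [0, 1] + [2 + 2 * i for i in range(self.ndim)] + \
                [3 + 2 * i for i in range(self.ndim)]
        return xr.transpose(order).reshape((n, c) + out_sp + (p ** self.ndim,))

    def forward(self, x, training=False, rng=None):
        for s in x.shape[2:]:
            if s % self.pool != 0:
                raise ValueError(
                    f"spatial extent {s} not divisible by pool size {self.pool}")
        self._in_shape = x.shape
        blocked = self._blocked(x)
        self._argmax = blocked.argmax(axis=-1)
        return np.take_along_axis(blocked, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c = self._in_shape[:2]
        p = self.pool
        out_sp = dy.shape[2:]
        dblock = np.zeros((n, c) + out_sp + (p ** self.ndim,), dtype=dy.dtype)
        np.put_along_axis(dblock, self._argmax[..., None], dy[..., None], axis=-1)
        dblock = dblock.reshape((n, c) + out_sp + (p,) * self.ndim)
        # inverse of the transpose used in _blocked
        order = [0, 1]
        for i in range(self.ndim):
            order += [2 + i, 2 + self.ndim + i]
        return dblock.transpose(order).reshape(self._in_shape)

    def output_shape(self, in_shape):
        return (in_shape[0],) + tuple(s // self.pool for s in in_shape[1:])


class PReLU(Layer):
    """Parametric rectifier with one learnable slope per channel."""

    def __init__(self, n_channels: int, init: float = 0.25) -> None:
        super().__init__()
        self.params = [np.full(n_channels, init, dtype=np.float32)]
        self.grads = [np.zeros(n_channels, dtype=np.float32)]
        self.param_decay = [False]

    def _slope_shape(self, x: np.ndarray) -> tuple[int, ...]:
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, training=False, rng=None):
        self._x = x
        a = self.params[0].reshape(self._slope_shape(x))
        return np.maximum(x, 0) + a * np.minimum(x, 0)

    def backward(self, dy):
        x = self._x
        a = self.params[0].reshape(self._slope_shape(x))
        neg = np.minimum(x, 0)
        axes = (0,) + tuple(range(2, x.ndim))
        self.grads[0][...] = (dy * neg).sum(axis=axes)
        return dy * np.where(x > 0, 1.0, 0.0) + dy * a * (x < 0)

    def output_shape(self, in_shape):
        return in_shape


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    def output_shape(self, in_shape):
        return in_shape


class Dense(Layer):
    """Fully connected layer, inputs ``(batch, in_features)``."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / in_features)
        w = rng.normal(0.0, scale, size=(in_features, out_features))
        self.params = [w.astype(np.float32), np.zeros(out_features, dtype=np.float32)]
        self.grads = [np.zeros_like(p) for p in self.params]
        self.param_decay = [True, False]

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.params[0].T

    def output_shape(self, in_shape):
        return (self.params[0].shape[1],)


class Dropout(Layer):
    """Inverted dropout: active only in training, identity in evaluation."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        self._mask = (rng.uniform(size=x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask

    def output_shape(self, in_shape):
        return in_shape


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def output_shape(self, in_shape):
        return (int(np.prod(in_shape)),)


class Sigmoid(Layer):
    def forward(self, x, training=False, rng=None):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)

    def output_shape(self, in_shape):
        return in_shape
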