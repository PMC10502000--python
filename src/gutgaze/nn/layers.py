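"""Building-block layers (2d and 3d) with explicit backward passes.

Tensors are (N, C, *spatial) float64.  Convolutions are stride-1 with same
padding; pooling and upsampling change spatial dimensions by exactly a
factor of 2, so input shapes must be divisible accordingly.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Param", "Conv", "ReLU", "BatchNorm", "Dropout", "MaxPool", "Upsample", "Softplus"]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)


_SPATIAL = "dhw"


def _einsum_specs(dims: int, k: int):
    sp = _SPATIAL[-dims:]
    kk = "ijk"[:dims]
    fwd = f"nc{sp}{kk},oc{kk}->no{sp}"
    dw = f"nc{sp}{kk},no{sp}->oc{kk}"
    dx = f"no{sp}{kk},oc{kk}->nc{sp}"
    return fwd, dw, dx


class Conv:
    """k^dims convolution, stride 1, zero same-padding (k odd)."""

    def __init__(self, in_ch: int, out_ch: int, dims: int, k: int = 3, rng=None):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * k**dims
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch) + (k,) * dims)
        self.w = Param("conv_w", w)
        self.b = Param("conv_b", np.zeros(out_ch))
        self.dims = dims
        self.k = k
        self._fwd, self._dw, self._dx = _einsum_specs(dims, k)
        self._xp: np.ndarray | None = None

    def _pad(self, x: np.ndarray) -> np.ndarray:
        p = self.k // 2
        pad = [(0, 0), (0, 0)] + [(p, p)] * self.dims
        return np.pad(x, pad)

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if self.k == 1:
            self._xp = x
            y = np.tensordot(
                self.w.value.reshape(self.w.value.shape[:2]), x, axes=([1], [1])
            ).swapaxes(0, 1)
        else:
            xp = self._pad(x)
            self._xp = xp
            win = sliding_window_view(xp, (self.k,) * self.dims, axis=tuple(range(2, 2 + self.dims)))
            y = np.einsum(self._fwd, win, self.w.value, optimize=True)
        return y + self.b.value.reshape((1, -1) + (1,) * self.dims)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        axes = (0,) + tuple(range(2, 2 + self.dims))
        self.b.grad += dy.sum(axis=axes)
        if self.k == 1:
            x = self._xp
            self.w.grad += np.tensordot(dy, x, axes=(list(axes), list(axes))).reshape(
                self.w.value.shape
            )
            dx = np.tensordot(
                self.w.value.reshape(self.w.value.shape[:2]).T, dy, axes=([1], [1])
            ).swapaxes(0, 1)
            return dx
        win = sliding_window_view(
            self._xp, (self.k,) * self.dims, axis=tuple(range(2, 2 + self.dims))
        )
        self.w.grad += np.einsum(self._dw, win, dy, optimize=True)
        wflip = self.w.value[(slice(None), slice(None)) + (slice(None, None, -1),) * self.dims]
        dyp = self._pad(dy)
        win_dy = sliding_window_view(dyp, (self.k,) * self.dims, axis=tuple(range(2, 2 + self.dims)))
        return np.einsum(self._dx, win_dy, wflip, optimize=True)

    def params(self) -> list[Param]:
        return [self.w, self.b]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)

    def params(self) -> list[Param]:
        return []


class Softplus:
    """softplus(x) = log(1 + e^x): smooth non-negative output activation."""

    def __init__(self):
        self._x = None

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._x = x
        return np.logaddexp(0.0, x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        sig = 1.0 / (1.0 + np.exp(-self._x))
        return dy * sig

    def params(self) -> list[Param]:
        return []


class BatchNorm:
    def __init__(self, ch: int, dims: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param("bn_gamma", np.ones(ch))
        self.beta = Param("bn_beta", np.zeros(ch))
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)
        self.momentum = momentum
        self.eps = eps
        self.dims = dims
        self._cache = None

    def _shape(self, v: np.ndarray) -> np.ndarray:
        return v.reshape((1, -1) + (1,) * self.dims)

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        axes = (0,) + tuple(range(2, 2 + self.dims))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - self._shape(mu)) / self._shape(std)
        self._cache = (xhat, std, axes, x.size // x.shape[1])
        return self._shape(self.gamma.value) * xhat + self._shape(self.beta.value)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, std, axes, n = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self._shape(self.gamma.value / std)
        mean_dy = self._shape(dy.mean(axis=axes))
        mean_dy_xhat = self._shape((dy * xhat).mean(axis=axes))
        return g * (dy - mean_dy - xhat * mean_dy_xhat)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class Dropout:
    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask

    def params(self) -> list[Param]:
        return []


class MaxPool:
    """2x pooling per spatial axis (shape must be even)."""

    def __init__(self, dims: int):
        self.dims = dims
        self._cache = None

    @staticmethod
    def _blocked(x: np.ndarray, dims: int) -> np.ndarray:
        shape = list(x.shape[:2])
        for s in x.shape[2:]:
            shape += [s // 2, 2]
        return x.reshape(shape)

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        b = self._blocked(x, self.dims)
        axes = tuple(3 + 2 * i for i in range(self.dims))
        y = b.max(axis=axes)
        # expand y back to block shape to build the routing mask
        ye = y
        for ax in axes:
            ye = np.expand_dims(ye, ax)
        mask = (b == ye).astype(float)
        mask /= mask.sum(axis=axes, keepdims=True)  # split gradient across ties
        self._cache = (mask, x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mask, xshape = self._cache
        axes = tuple(3 + 2 * i for i in range(self.dims))
        dye = dy
        for ax in axes:
            dye = np.expand_dims(dye, ax)
        return (mask * dye).reshape(xshape)

    def params(self) -> list[Param]:
        return []


class Upsample:
    """Nearest-neighbour 2x upsampling per spatial axis."""

    def __init__(self, dims: int):
        self.dims = dims

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        y = x
        for i in range(self.dims):
            y = np.repeat(y, 2, axis=2 + i)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b = MaxPool._blocked(dy, self.dims)
        axes = tuple(3 + 2 * i for i in range(self.dims))
        return b.sum(axis=axes)

    def params(self) -> list[Param]:
        return []
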