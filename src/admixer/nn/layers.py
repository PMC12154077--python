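"""Layer forward/backward implementations (NHWC tensors).

Convolutions use an im2col view built with ``sliding_window_view`` and
a single matrix multiply; backward scatters gradients back with a small
loop over kernel offsets.  The separable convolution is a per-channel
(depthwise) spatial filter followed by a 1x1 cross-channel (pointwise)
mix, with a single bias after the pointwise step and no depthwise bias.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .initializers import make_initializer

__all__ = ["build_layer", "Layer"]


def _windows(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N, oh, ow, kh, kw, C) sliding windows of an NHWC tensor."""
    v = sliding_window_view(x, (kh, kw), axis=(1, 2))  # (N, oh', ow', C, kh, kw)
    v = v[:, ::stride, ::stride]
    return np.moveaxis(v, 3, 5)  # (N, oh, ow, kh, kw, C)


def _scatter_windows(dwin: np.ndarray, in_shape, kh: int, kw: int, stride: int) -> np.ndarray:
    """Adjoint of `_windows`: accumulate window gradients onto the input."""
    N, H, W, C = in_shape
    oh, ow = dwin.shape[1], dwin.shape[2]
    dx = np.zeros(in_shape, dtype=dwin.dtype)
    for p in range(kh):
        for q in range(kw):
            dx[:, p : p + oh * stride : stride, q : q + ow * stride : stride, :] += dwin[
                :, :, :, p, q, :
            ]
    return dx


class Layer:
    """Base layer: parameters in ``params``, gradients in ``grads``."""

    def __init__(self, spec, in_shape):
        self.spec = spec
        self.in_shape = tuple(in_shape)
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def param_count(self) -> int:
        return sum(int(p.size) for p in self.params.values())


def _relu_backward(dout, pre):
    return dout * (pre > 0)


class Conv2D(Layer):
    def __init__(self, spec, in_shape, rng):
        super().__init__(spec, in_shape)
        kh, kw = spec.kernel
        c = in_shape[2]
        f = spec.filters
        fan_in, fan_out = kh * kw * c, kh * kw * f
        init = make_initializer(spec.initializer, fan_in, fan_out)
        self.params["W"] = init(rng, (kh * kw * c, f))
        self.params["b"] = np.zeros(f)
        self.kh, self.kw, self.stride = kh, kw, spec.stride
        self.relu = spec.activation == "relu"

    def forward(self, x, training):
        self._x_shape = x.shape
        cols = _windows(x, self.kh, self.kw, self.stride)
        N, oh, ow = cols.shape[:3]
        self._cols = cols.reshape(N, oh, ow, -1)
        z = self._cols @ self.params["W"] + self.params["b"]
        self._pre = z
        return np.maximum(z, 0.0) if self.relu else z

    def backward(self, dout):
        dz = _relu_backward(dout, self._pre) if self.relu else dout
        N, oh, ow, f = dz.shape
        k = self._cols.shape[-1]
        self.grads["W"] = self._cols.reshape(-1, k).T @ dz.reshape(-1, f)
        self.grads["b"] = dz.sum(axis=(0, 1, 2))
        dcols = (dz @ self.params["W"].T).reshape(
            N, oh, ow, self.kh, self.kw, self.in_shape[2]
        )
        return _scatter_windows(dcols, self._x_shape, self.kh, self.kw, self.stride)


class SeparableConv2D(Layer):
    """Depthwise kernel (kh, kw, C), pointwise (C, F), bias (F)."""

    def __init__(self, spec, in_shape, rng):
        super().__init__(spec, in_shape)
        kh, kw = spec.kernel
        c = in_shape[2]
        f = spec.filters
        init_dw = make_initializer(spec.initializer, kh * kw, kh * kw)
        init_pw = make_initializer(spec.initializer, c, f)
        self.params["Wd"] = init_dw(rng, (kh, kw, c))
        self.params["Wp"] = init_pw(rng, (c, f))
        self.params["b"] = np.zeros(f)
        self.kh, self.kw, self.stride = kh, kw, spec.stride
        self.relu = spec.activation == "relu"

    def forward(self, x, training):
        self._x_shape = x.shape
        win = _windows(x, self.kh, self.kw, self.stride)
        self._win = win
        d = np.einsum("nijpqc,pqc->nijc", win, self.params["Wd"])
        self._d = d
        z = d @ self.params["Wp"] + self.params["b"]
        self._pre = z
        return np.maximum(z, 0.0) if self.relu else z

    def backward(self, dout):
        dz = _relu_backward(dout, self._pre) if self.relu else dout
        N, oh, ow, f = dz.shape
        c = self.in_shape[2]
        self.grads["b"] = dz.sum(axis=(0, 1, 2))
        self.grads["Wp"] = self._d.reshape(-1, c).T @ dz.reshape(-1, f)
        dd = dz @ self.params["Wp"].T  # (N, oh, ow, C)
        self.grads["Wd"] = np.einsum("nijpqc,nijc->pqc", self._win, dd)
        dwin = dd[:, :, :, None, None, :] * self.params["Wd"][None, None, None]
        return _scatter_windows(dwin, self._x_shape, self.kh, self.kw, self.stride)


class Pool2D(Layer):
    def __init__(self, spec, in_shape, mode):
        super().__init__(spec, in_shape)
        self.f = spec.kernel[0] if spec.kernel else 2
        self.stride = 2 if (spec.kernel is None and spec.stride == 1) else spec.stride
        self.mode = mode

    def forward(self, x, training):
        self._x_shape = x.shape
        win = _windows(x, self.f, self.f, self.stride)  # (N,oh,ow,f,f,C)
        if self.mode == "avg":
            return win.mean(axis=(3, 4))
        m = win.max(axis=(3, 4))
        mask = win == m[:, :, :, None, None, :]
        # split gradient equally among tied maxima
        self._mask = mask / mask.sum(axis=(3, 4), keepdims=True)
        return m

    def backward(self, dout):
        if self.mode == "avg":
            dwin = np.broadcast_to(
                dout[:, :, :, None, None, :] / (self.f * self.f),
                dout.shape[:3] + (self.f, self.f, dout.shape[3]),
            )
        else:
            dwin = dout[:, :, :, None, None, :] * self._mask
        return _scatter_windows(dwin, self._x_shape, self.f, self.f, self.stride)


class Dropout(Layer):
    def __init__(self, spec, in_shape, rng):
        super().__init__(spec, in_shape)
        self.rate = spec.rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, training):
        self._x_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._x_shape)


class Dense(Layer):
    def __init__(self, spec, in_shape, rng):
        super().__init__(spec, in_shape)
        fan_in, fan_out = in_shape[0], spec.units
        init = make_initializer(spec.initializer, fan_in, fan_out)
        self.params["W"] = init(rng, (fan_in, fan_out))
        self.params["b"] = np.zeros(fan_out)
        self.relu = spec.activation == "relu"

    def forward(self, x, training):
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        self._pre = z
        return np.maximum(z, 0.0) if self.relu else z

    def backward(self, dout):
        dz = _relu_backward(dout, self._pre) if self.relu else dout
        self.grads["W"] = self._x.T @ dz
        self.grads["b"] = dz.sum(axis=0)
        return dz @ self.params["W"].T


class Softmax(Layer):
    def forward(self, x, training):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        self._p = e / e.sum(axis=-1, keepdims=True)
        return self._p

    def backward(self, dout):
        p = self._p
        return (dout - (dout * p).sum(axis=-1, keepdims=True)) * p


def build_layer(spec, in_shape, rng: np.random.Generator) -> Layer:
    kind = spec.kind
    if kind == "conv":
        return Conv2D(spec, in_shape, rng)
    if kind == "separable_conv":
        return SeparableConv2D(spec, in_shape, rng)
    if kind == "avg_pool":
        return Pool2D(spec, in_shape, "avg")
    if kind == "max_pool":
        return Pool2D(spec, in_shape, "max")
    if kind == "dropout":
        return Dropout(spec, in_shape, rng)
    if kind == "flatten":
        return Flatten(spec, in_shape)
    if kind == "dense":
        return Dense(spec, in_shape, rng)
    if kind == "softmax":
        return Softmax(spec, in_shape)
    raise ValueError(f"unknown layer kind {kind!r}")
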