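"""Trainable and stateless layers with explicit forward/backward passes."""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def _im2col(x: np.ndarray, kernel: int, stride: int, pad: int
            ) -> Tuple[np.ndarray, int, int]:
    """Unfold NCHW into (N, C*k*k, oh*ow) columns."""
    n, c, h, w = x.shape
    oh = (h + 2 * pad - kernel) // stride + 1
    ow = (w + 2 * pad - kernel) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, kernel, kernel, oh, ow), dtype=x.dtype)
    for i in range(kernel):
        for j in range(kernel):
            cols[:, :, i, j] = xp[:, :, i:i + stride * oh:stride,
                                  j:j + stride * ow:stride]
    return cols.reshape(n, c * kernel * kernel, oh * ow), oh, ow


def _col2im(dcols: np.ndarray, x_shape: Tuple[int, ...], kernel: int,
            stride: int, pad: int, oh: int, ow: int) -> np.ndarray:
    """Fold (N, C*k*k, oh*ow) column gradients back into NCHW (scatter-add)."""
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(n, c, kernel, kernel, oh, ow)
    for i in range(kernel):
        for j in range(kernel):
            dxp[:, :, i:i + stride * oh:stride,
                j:j + stride * ow:stride] += d[:, :, i, j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Layer:
    params: List[Param] = []

    def forward(self, inputs: Sequence[np.ndarray], train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> List[np.ndarray]:
        raise NotImplementedError


class Conv2d(Layer):
    """Grouped 2D convolution (cross-correlation) via im2col."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int, pad: int, groups: int, bias: bool,
                 rng: np.random.Generator):
        self.cin, self.cout = in_channels, out_channels
        self.k, self.stride, self.pad, self.groups = kernel, stride, pad, groups
        fan_in = (in_channels // groups) * kernel * kernel
        fan_out = (out_channels // groups) * kernel * kernel
        limit = np.sqrt(6.0 / (fan_in + fan_out))  # Xavier/Glorot uniform
        w = rng.uniform(-limit, limit,
                        (out_channels, in_channels // groups, kernel, kernel))
        self.weight = Param(w)
        self.bias = Param(np.zeros(out_channels)) if bias else None
        self.params = [self.weight] + ([self.bias] if bias else [])

    def forward(self, inputs, train):
        (x,) = inputs
        cols, oh, ow = _im2col(x, self.k, self.stride, self.pad)
        n = x.shape[0]
        g = self.groups
        cpg_in = self.cin // g * self.k * self.k
        cpg_out = self.cout // g
        self._cache = (x.shape, cols, oh, ow)
        out = np.empty((n, self.cout, oh * ow))
        wmat = self.weight.value.reshape(self.cout, -1)
        for gi in range(g):
            wg = wmat[gi * cpg_out:(gi + 1) * cpg_out]
            cg = cols[:, gi * cpg_in:(gi + 1) * cpg_in]
            out[:, gi * cpg_out:(gi + 1) * cpg_out] = np.einsum(
                "oc,ncp->nop", wg, cg, optimize=True)
        if self.bias is not None:
            out += self.bias.value[None, :, None]
        return out.reshape(n, self.cout, oh, ow)

    def backward(self, grad):
        x_shape, cols, oh, ow = self._cache
        n = x_shape[0]
        g = self.groups
        cpg_in = self.cin // g * self.k * self.k
        cpg_out = self.cout // g
        gflat = grad.reshape(n, self.cout, oh * ow)
        wmat = self.weight.value.reshape(self.cout, -1)
        dcols = np.empty_like(cols)
        dw = np.empty_like(wmat)
        for gi in range(g):
            sl_o = slice(gi * cpg_out, (gi + 1) * cpg_out)
            sl_i = slice(gi * cpg_in, (gi + 1) * cpg_in)
            dw[sl_o] = np.einsum("nop,ncp->oc", gflat[:, sl_o], cols[:, sl_i],
                                 optimize=True)
            dcols[:, sl_i] = np.einsum("oc,nop->ncp", wmat[sl_o],
                                       gflat[:, sl_o], optimize=True)
        self.weight.grad += dw.reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += gflat.sum(axis=(0, 2))
        return [_col2im(dcols, x_shape, self.k, self.stride, self.pad, oh, ow)]


class BatchNorm2d(Layer):
    """Batch normalization over (N, H, W) with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.9,
                 eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.params = [self.gamma, self.beta]
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps
        self.collecting = False
        self._collected: List[Tuple[np.ndarray, np.ndarray]] = []

    def start_collect(self) -> None:
        """Begin finalization: subsequent forwards use and record batch stats."""
        self.collecting = True
        self._collected = []

    def finish_collect(self) -> None:
        """Freeze running statistics to the mean of the collected batches."""
        if self._collected:
            self.running_mean = np.mean([m for m, _ in self._collected], axis=0)
            self.running_var = np.mean([v for _, v in self._collected], axis=0)
        self.collecting = False
        self._collected = []

    def forward(self, inputs, train):
        (x,) = inputs
        if self.collecting:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self._collected.append((mean, var))
        elif train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, train, x.shape)
        return self.gamma.value[None, :, None, None] * xhat \
            + self.beta.value[None, :, None, None]

    def backward(self, grad):
        xhat, inv_std, train, shape = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        gscaled = grad * self.gamma.value[None, :, None, None]
        if not train:
            return [gscaled * inv_std[None, :, None, None]]
        m = shape[0] * shape[2] * shape[3]
        dxhat = gscaled
        dx = (inv_std[None, :, None, None] / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True))
        return [dx]


class ReLU(Layer):
    def forward(self, inputs, train):
        (x,) = inputs
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return [grad * self._mask]


def _pool_geometry(h: int, w: int, k: int, stride: int, ceil_mode: bool
                   ) -> Tuple[int, int, int, int]:
    if ceil_mode:
        oh = -(-(h - k) // stride) + 1
        ow = -(-(w - k) // stride) + 1
    else:
        oh = (h - k) // stride + 1
        ow = (w - k) // stride + 1
    pad_h = max(0, (oh - 1) * stride + k - h)
    pad_w = max(0, (ow - 1) * stride + k - w)
    return oh, ow, pad_h, pad_w


class MaxPool2d(Layer):
    def __init__(self, kernel: int, stride: int, ceil_mode: bool):
        self.k, self.stride, self.ceil_mode = kernel, stride, ceil_mode

    def forward(self, inputs, train):
        (x,) = inputs
        n, c, h, w = x.shape
        oh, ow, ph, pw = _pool_geometry(h, w, self.k, self.stride,
                                        self.ceil_mode)
        xp = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)),
                    constant_values=-np.inf)
        cols, _, _ = _im2col(xp, self.k, self.stride, 0)
        win = cols.reshape(n, c, self.k * self.k, oh * ow)
        self._argmax = win.argmax(axis=2)
        self._cache = (x.shape, (h + ph, w + pw), oh, ow)
        return win.max(axis=2).reshape(n, c, oh, ow)

    def backward(self, grad):
        x_shape, padded_hw, oh, ow = self._cache
        n, c = x_shape[:2]
        gflat = grad.reshape(n, c, oh * ow)
        dcols = np.zeros((n, c, self.k * self.k, oh * ow))
        np.put_along_axis(dcols, self._argmax[:, :, None, :], gflat[:, :, None, :],
                          axis=2)
        dxp = _col2im(dcols.reshape(n, c * self.k * self.k, oh * ow),
                      (n, c) + padded_hw, self.k, self.stride, 0, oh, ow)
        return [dxp[:, :, :x_shape[2], :x_shape[3]]]


class AvgPool2d(Layer):
    """Average pooling; ceil-mode windows past the border average only the
    pixels actually inside the input."""

    def __init__(self, kernel: int, stride: int, ceil_mode: bool):
        self.k, self.stride, self.ceil_mode = kernel, stride, ceil_mode

    def forward(self, inputs, train):
        (x,) = inputs
        n, c, h, w = x.shape
        oh, ow, ph, pw = _pool_geometry(h, w, self.k, self.stride,
                                        self.ceil_mode)
        xp = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)))
        cols, _, _ = _im2col(xp, self.k, self.stride, 0)
        win = cols.reshape(n, c, self.k * self.k, oh * ow)
        ones = np.pad(np.ones((1, 1, h, w)), ((0, 0), (0, 0), (0, ph), (0, pw)))
        ocols, _, _ = _im2col(ones, self.k, self.stride, 0)
        counts = ocols.reshape(1, 1, self.k * self.k, oh * ow).sum(axis=2)
        self._cache = (x.shape, (h + ph, w + pw), oh, ow, counts)
        return (win.sum(axis=2) / counts).reshape(n, c, oh, ow)

    def backward(self, grad):
        x_shape, padded_hw, oh, ow, counts = self._cache
        n, c = x_shape[:2]
        gflat = grad.reshape(n, c, oh * ow) / counts
        dcols = np.broadcast_to(gflat[:, :, None, :],
                                (n, c, self.k * self.k, oh * ow))
        dxp = _col2im(dcols.reshape(n, c * self.k * self.k, oh * ow),
                      (n, c) + padded_hw, self.k, self.stride, 0, oh, ow)
        return [dxp[:, :, :x_shape[2], :x_shape[3]]]


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, inputs, train):
        (x,) = inputs
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return [grad]
        return [grad * self._mask]


class Concat(Layer):
    """Channel-wise concatenation of several inputs."""

    def forward(self, inputs, train):
        self._splits = np.cumsum([x.shape[1] for x in inputs])[:-1]
        return np.concatenate(inputs, axis=1)

    def backward(self, grad):
        return list(np.split(grad, self._splits, axis=1))


class Add(Layer):
    def forward(self, inputs, train):
        self._n = len(inputs)
        out = inputs[0].copy()
        for x in inputs[1:]:
            out += x
        return out

    def backward(self, grad):
        return [grad] * self._n


class Flatten(Layer):
    def forward(self, inputs, train):
        (x,) = inputs
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return [grad.reshape(self._shape)]


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, bias: bool,
                 rng: np.random.Generator):
        limit = np.sqrt(6.0 / (in_features + out_features))
        self.weight = Param(rng.uniform(-limit, limit,
                                        (in_features, out_features)))
        self.bias = Param(np.zeros(out_features)) if bias else None
        self.params = [self.weight] + ([self.bias] if bias else [])

    def forward(self, inputs, train):
        (x,) = inputs
        self._x = x
        out = x @ self.weight.value
        if self.bias is not None:
            out = out + self.bias.value
        return out

    def backward(self, grad):
        self.weight.grad += self._x.T @ grad
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=0)
        return [grad @ self.weight.value.T]


class Softmax(Layer):
    def forward(self, inputs, train):
        (x,) = inputs
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        self._p = e / e.sum(axis=1, keepdims=True)
        return self._p

    def backward(self, grad):
        p = self._p
        return [p * (grad - (grad * p).sum(axis=1, keepdims=True))]
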