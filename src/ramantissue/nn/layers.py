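"""Minimal 1-D neural-network layers with explicit forward/backward passes.

All layers operate on arrays of shape (batch, channels, length) in float64.
Each layer caches what its backward pass needs during ``forward`` and
returns the gradient with respect to its input from ``backward``; trainable
tensors are exposed as :class:`Param` objects so an optimizer can walk
``layer.params()`` generically.

The implementation is deliberately small and deterministic: convolutions
are evaluated by gathering kernel taps into a column tensor (an im2col of
at most ``kernel`` strided slices) followed by one matmul, so the whole
network runs on plain numpy with reproducible CPU arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "MaxPool1d",
    "GlobalAvgPool1d",
    "Flatten",
    "Linear",
    "Sequential",
    "softmax",
    "conv_output_length",
]


@dataclass
class Param:
    """A trainable tensor with its gradient and optimizer state slot."""

    value: np.ndarray
    grad: np.ndarray = field(init=False)
    name: str = ""

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=float)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    """Base class: stateless unless a subclass adds parameters/caches."""

    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def conv_output_length(length: int, kernel: int, stride: int, padding: int) -> int:
    """Output length of a 1-D convolution/pool with the given geometry."""
    return (length + 2 * padding - kernel) // stride + 1


def _im2col(xp: np.ndarray, kernel: int, stride: int, out_len: int) -> np.ndarray:
    """Gather kernel taps: (N, C, Lp) -> (N, C, kernel, out_len)."""
    n, c, _ = xp.shape
    cols = np.empty((n, c, kernel, out_len), dtype=xp.dtype)
    for j in range(kernel):
        cols[:, :, j, :] = xp[:, :, j : j + stride * out_len : stride]
    return cols


class Conv1d(Layer):
    """1-D convolution with 'same'-style padding (``padding = kernel // 2``).

    Bias is off by default because a batch-norm layer follows every
    convolution in the residual blocks.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, bias: bool = False,
                 rng: Optional[np.random.Generator] = None, name: str = "conv"):
        if kernel < 1 or stride < 1:
            raise ValueError("kernel and stride must be >= 1")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = kernel // 2
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel
        # He-normal initialization, appropriate for ReLU stacks.
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels, kernel))
        self.weight = Param(w, name=f"{name}.weight")
        self.bias = Param(np.zeros(out_channels), name=f"{name}.bias") if bias else None
        self._cache = None

    def params(self) -> List[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def output_length(self, length: int) -> int:
        return conv_output_length(length, self.kernel, self.stride, self.padding)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, length = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        out_len = self.output_length(length)
        if out_len < 1:
            raise ValueError("input too short for this convolution")
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p))) if p else x
        cols = _im2col(xp, self.kernel, self.stride, out_len)
        # (N, out_len, C*k) @ (C*k, O) -> (N, out_len, O)
        flat = cols.reshape(n, c * self.kernel, out_len).transpose(0, 2, 1)
        w2 = self.weight.value.reshape(self.out_channels, c * self.kernel)
        y = (flat @ w2.T).transpose(0, 2, 1)
        if self.bias is not None:
            y += self.bias.value[None, :, None]
        if training:
            self._cache = (flat, xp.shape, length)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        flat, xp_shape, length = self._cache
        n = dy.shape[0]
        out_len = dy.shape[2]
        ck = self.in_channels * self.kernel
        w2 = self.weight.value.reshape(self.out_channels, ck)
        dyt = dy.transpose(0, 2, 1)  # (N, out_len, O)
        # dW: sum over batch and positions.
        dw = np.einsum("nlo,nlk->ok", dyt, flat, optimize=True)
        self.weight.grad += dw.reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2))
        dcols = (dyt @ w2).transpose(0, 2, 1).reshape(
            n, self.in_channels, self.kernel, out_len
        )
        dxp = np.zeros(xp_shape, dtype=dy.dtype)
        for j in range(self.kernel):
            dxp[:, :, j : j + self.stride * out_len : self.stride] += dcols[:, :, j, :]
        p = self.padding
        self._cache = None
        return dxp[:, :, p : p + length] if p else dxp


class BatchNorm1d(Layer):
    """Batch normalization over (batch, length) per channel."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn"):
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(np.ones(channels), name=f"{name}.gamma")
        self.beta = Param(np.zeros(channels), name=f"{name}.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def params(self) -> List[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
        y = self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]
        if training:
            self._cache = (xhat, inv_std)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self._cache = None
        self.gamma.grad += np.sum(dy * xhat, axis=(0, 2))
        self.beta.grad += dy.sum(axis=(0, 2))
        dxhat = dy * self.gamma.value[None, :, None]
        # Standard batch-norm backward, reduced over batch and length.
        return inv_std[None, :, None] * (
            dxhat
            - dxhat.mean(axis=(0, 2), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2), keepdims=True)
        )


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mask, self._mask = self._mask, None
        return dy * mask


class MaxPool1d(Layer):
    """Max pooling with reflected-zero padding (pad value -inf)."""

    def __init__(self, kernel: int = 3, stride: int = 2, padding: int = 1):
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        self._cache = None

    def output_length(self, length: int) -> int:
        return conv_output_length(length, self.kernel, self.stride, self.padding)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, length = x.shape
        out_len = self.output_length(length)
        if out_len < 1:
            raise ValueError("input too short for this pooling layer")
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)), constant_values=-np.inf) if p else x
        cols = _im2col(xp, self.kernel, self.stride, out_len)
        arg = cols.argmax(axis=2)
        y = np.take_along_axis(cols, arg[:, :, None, :], axis=2)[:, :, 0, :]
        if training:
            self._cache = (arg, xp.shape, length, out_len)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        arg, xp_shape, length, out_len = self._cache
        self._cache = None
        dxp = np.zeros(xp_shape, dtype=dy.dtype)
        for j in range(self.kernel):
            sel = arg == j
            if np.any(sel):
                dxp[:, :, j : j + self.stride * out_len : self.stride] += dy * sel
        p = self.padding
        return dxp[:, :, p : p + length] if p else dxp


class GlobalAvgPool1d(Layer):
    """Adaptive average pooling to one position per channel: (N,C,L) -> (N,C)."""

    def __init__(self) -> None:
        self._length = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        length, self._length = self._length, None
        return np.repeat(dy[:, :, None], length, axis=2) / length


class Flatten(Layer):
    def __init__(self) -> None:
        self._shape = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        shape, self._shape = self._shape, None
        return dy.reshape(shape)


class Linear(Layer):
    """Fully connected layer on (N, features)."""

    def __init__(self, in_features: int, out_features: int,
                 rng: Optional[np.random.Generator] = None, name: str = "fc"):
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / np.sqrt(in_features)
        w = rng.uniform(-bound, bound, size=(out_features, in_features))
        b = rng.uniform(-bound, bound, size=out_features)
        self.weight = Param(w, name=f"{name}.weight")
        self.bias = Param(b, name=f"{name}.bias")
        self._cache = None

    def params(self) -> List[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._cache = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, self._cache = self._cache, None
        self.weight.grad += dy.T @ x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value


class Sequential(Layer):
    """Run layers in order; backward in reverse."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self) -> List[Param]:
        out: List[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilized."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
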