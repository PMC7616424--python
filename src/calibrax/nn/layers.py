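"""Neural-network building blocks on top of the autodiff engine.

Layers follow the familiar Module convention: parameters are Tensors with
``requires_grad=True``, ``module(x)`` runs the forward pass, and
``module.parameters()`` yields every trainable Tensor.  Convolution is
implemented with an im2col/col2im pair so the heavy lifting is a single
BLAS matmul per layer.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autodiff import Tensor

__all__ = [
    "Module",
    "Linear",
    "Conv2d",
    "MaxPool2d",
    "GlobalAvgPool2d",
    "BatchNorm2d",
    "ReLU",
    "Flatten",
    "Sequential",
]


class Module:
    """Base class: parameter discovery, train/eval mode propagation."""

    training: bool = True

    def parameters(self):
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                yield v
            elif isinstance(v, Module):
                yield from v.parameters()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.parameters()

    def modules(self):
        yield self
        for v in vars(self).values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def state_arrays(self) -> list[np.ndarray]:
        """Flat list of parameter arrays (views), in discovery order."""
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays):
        for p, a in zip(self.parameters(), arrays, strict=True):
            p.data[...] = a


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator,
        dtype=np.float64,
    ):
        scale = np.sqrt(2.0 / in_features)
        self.weight = Tensor(
            rng.normal(0.0, scale, (in_features, out_features)).astype(dtype), True
        )
        self.bias = Tensor(np.zeros(out_features, dtype=dtype), True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    # x: (N, C, H, W) -> (N, OH, OW, C*kh*kw)
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, oh, ow = win.shape[:4]
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh, ow, c * kh * kw)


class Conv2d(Module):
    """2-D convolution (cross-correlation), NCHW layout."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
        dtype=np.float64,
    ):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, scale, (fan_in, out_channels)).astype(dtype), True)
        self.bias = Tensor(np.zeros(out_channels, dtype=dtype), True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        k, s, p = self.kernel_size, self.stride, self.padding
        n, c, h, w = x.shape
        if h + 2 * p < k or w + 2 * p < k:
            raise ValueError(
                f"input {h}x{w} smaller than the {k}x{k} receptive-field minimum"
            )
        xd = x.data
        if p:
            xd = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = _im2col(xd, k, k, s)  # (N, OH, OW, C*k*k)
        oh, ow = cols.shape[1], cols.shape[2]
        cols2 = cols.reshape(-1, cols.shape[-1])
        weight, bias = self.weight, self.bias
        out_data = cols2 @ weight.data
        if bias is not None:
            out_data = out_data + bias.data
        out_data = out_data.reshape(n, oh, ow, self.out_channels).transpose(0, 3, 1, 2)

        parents = (x, weight) + ((bias,) if bias is not None else ())

        def backward(g):
            gflat = g.transpose(0, 2, 3, 1).reshape(-1, self.out_channels)
            if weight.requires_grad:
                weight._accum(cols2.T @ gflat)
            if bias is not None and bias.requires_grad:
                bias._accum(gflat.sum(axis=0))
            if x.requires_grad:
                dcols = (gflat @ weight.data.T).reshape(n, oh, ow, c, k, k)
                dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=g.dtype)
                for i in range(k):
                    for j in range(k):
                        dxp[:, :, i : i + oh * s : s, j : j + ow * s : s] += (
                            dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                        )
                x._accum(dxp[:, :, p : p + h, p : p + w] if p else dxp)

        return Tensor._from_op(out_data, parents, backward)


class MaxPool2d(Module):
    """Non-overlapping max pooling; input H, W must be divisible by the size."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x: Tensor) -> Tensor:
        s = self.size
        n, c, h, w = x.shape
        if h % s or w % s:
            raise ValueError(f"pooling size {s} does not divide input {h}x{w}")
        win = x.data.reshape(n, c, h // s, s, w // s, s)
        out_data = win.max(axis=(3, 5))
        mask = win == out_data[:, :, :, None, :, None]
        counts = mask.sum(axis=(3, 5), keepdims=True)

        def backward(g):
            if x.requires_grad:
                gwin = mask * (g[:, :, :, None, :, None] / counts)
                x._accum(gwin.reshape(n, c, h, w))

        return Tensor._from_op(out_data, (x,), backward)


class GlobalAvgPool2d(Module):
    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[:2]
        return x.reshape(n, c, -1).mean(axis=2)


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel, with running stats."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float64):
        self.gamma = Tensor(np.ones(channels, dtype=dtype), True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), True)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        shape = (1, -1, 1, 1)
        if self.training:
            mu = x.mean(axis=0, keepdims=True).mean(axis=2, keepdims=True).mean(
                axis=3, keepdims=True
            )
            xc = x - mu
            var = (xc * xc).mean(axis=0, keepdims=True).mean(
                axis=2, keepdims=True
            ).mean(axis=3, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            xhat = xc / (var + self.eps).sqrt()
        else:
            xhat = (x - self.running_mean.reshape(shape)) / np.sqrt(
                self.running_var.reshape(shape) + self.eps
            )
        return xhat * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.shape[0], -1)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
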