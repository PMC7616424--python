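"""Classifier architectures: a low-capacity LeNet-style CNN and a
higher-capacity 18-layer residual network adapted to small grayscale inputs.

Both return raw logits of shape (n, K); the interpretation of the logits
(SoftMax probabilities or Dirichlet evidence) is the head's job and lives
outside the network.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .layers import (
    BatchNorm2d,
    Conv2d,
    Flatten,
    GlobalAvgPool2d,
    Linear,
    MaxPool2d,
    Module,
    ReLU,
    Sequential,
)

__all__ = ["LeNet", "ResNetSmall", "build_model"]


class LeNet(Module):
    """Two conv+pool blocks followed by two dense layers (LeNet-5 style)."""

    def __init__(self, input_shape: tuple[int, int, int], num_classes: int, rng, dtype=np.float64):
        h, w, c = input_shape
        if h < 12 or w < 12:
            raise ValueError(
                f"input {h}x{w} below the 12x12 receptive-field minimum of this stack"
            )
        self.features = Sequential(
            Conv2d(c, 6, 5, rng, padding=2, dtype=dtype),
            ReLU(),
            MaxPool2d(2),
            Conv2d(6, 16, 5, rng, dtype=dtype),
            ReLU(),
            MaxPool2d(2),
            Flatten(),
        )
        fh = (h // 2 - 4) // 2
        fw = (w // 2 - 4) // 2
        self.classifier = Sequential(
            Linear(16 * fh * fw, 120, rng, dtype=dtype),
            ReLU(),
            Linear(120, 84, rng, dtype=dtype),
            ReLU(),
            Linear(84, num_classes, rng, dtype=dtype),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.classifier(self.features(x))


class BasicBlock(Module):
    def __init__(self, in_ch: int, out_ch: int, stride: int, rng, dtype=np.float64):
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng, stride=stride, padding=1, bias=False, dtype=dtype)
        self.bn1 = BatchNorm2d(out_ch, dtype=dtype)
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng, padding=1, bias=False, dtype=dtype)
        self.bn2 = BatchNorm2d(out_ch, dtype=dtype)
        if stride != 1 or in_ch != out_ch:
            self.down_conv = Conv2d(in_ch, out_ch, 1, rng, stride=stride, bias=False, dtype=dtype)
            self.down_bn = BatchNorm2d(out_ch, dtype=dtype)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out))
        skip = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return (out + skip).relu()


class ResNetSmall(Module):
    """18-layer residual topology (stem + 8 basic blocks + linear head),
    channel widths scaled for small grayscale images.  Spatial downsampling
    stops once the feature map would drop below 8x8."""

    def __init__(
        self,
        input_shape: tuple[int, int, int],
        num_classes: int,
        rng,
        widths: tuple[int, ...] = (16, 32, 64, 128),
        dtype=np.float64,
    ):
        h, w, c = input_shape
        if h < 8 or w < 8:
            raise ValueError(f"input {h}x{w} below the 8x8 minimum for the residual stack")
        self.stem = Sequential(
            Conv2d(c, widths[0], 3, rng, padding=1, bias=False, dtype=dtype),
            BatchNorm2d(widths[0], dtype=dtype),
            ReLU(),
        )
        blocks = []
        in_ch = widths[0]
        size = min(h, w)
        for stage, out_ch in enumerate(widths):
            stride = 1
            if stage > 0 and size // 2 >= 8:
                stride = 2
                size //= 2
            blocks.append(BasicBlock(in_ch, out_ch, stride, rng, dtype=dtype))
            blocks.append(BasicBlock(out_ch, out_ch, 1, rng, dtype=dtype))
            in_ch = out_ch
        self.blocks = blocks
        self.pool = GlobalAvgPool2d()
        self.fc = Linear(in_ch, num_classes, rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        x = self.stem(x)
        for b in self.blocks:
            x = b(x)
        return self.fc(self.pool(x))


def build_model(
    capacity: str,
    input_shape: tuple[int, int, int],
    num_classes: int,
    seed: int = 0,
    dtype=np.float64,
) -> Module:
    """Construct a classifier network.

    Parameters
    ----------
    capacity : {"low", "high"}
        "low" gives the LeNet-style stack, "high" the 18-layer residual net.
    input_shape : (height, width, channels)
    num_classes : K >= 2
    seed : weight-initialization seed
    dtype : parameter dtype; float32 roughly halves training time
    """
    if num_classes < 2:
        raise ValueError("num_classes must be >= 2")
    rng = np.random.default_rng(seed)
    if capacity == "low":
        return LeNet(input_shape, num_classes, rng, dtype=dtype)
    if capacity == "high":
        return ResNetSmall(input_shape, num_classes, rng, dtype=dtype)
    raise ValueError(f"unknown capacity {capacity!r}; expected 'low' or 'high'")
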