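"""Residual networks with optional in-block dropout.

Two backbones are provided:

* ``resnet50`` — the standard Bottleneck stack (3-4-6-3 blocks, widths
  64/128/256/512, expansion 4) with a 7x7/2 stem and 3x3/2 max pool.
* ``resnet18_lite`` — a narrow BasicBlock stack for desk-scale work: a 3x3 stem
  followed by one BasicBlock per stage with configurable base width.  It shares
  every structural convention with the full backbone (residual wiring, BN
  placement, dropout sites), differing only in depth and width.

When ``dropout_rate > 0`` and dropout-in-blocks is enabled, an inverted-dropout
layer follows each in-block ReLU activation.  Keeping those layers active at
inference (the Monte-Carlo mode of the :class:`~pcgscreen.nn.layers.Context`)
yields stochastic forward passes whose mean and spread approximate the Bayesian
posterior predictive.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    AvgPool2d,
    BatchNorm2d,
    Context,
    Conv2d,
    Dropout,
    GlobalAvgPool2d,
    Linear,
    MaxPool2d,
    Module,
    ReLU,
    Sequential,
)


class _ResidualBlock(Module):
    """Shared residual wiring: main path + identity/projection shortcut."""

    def __init__(self):
        super().__init__()
        self.main: Sequential
        self.downsample: Sequential | None = None
        self.relu_out = ReLU()
        self.drop_out: Dropout | None = None

    def forward(self, x: np.ndarray, ctx: Context) -> np.ndarray:
        out = self.main.forward(x, ctx)
        skip = self.downsample.forward(x, ctx) if self.downsample is not None else x
        out = self.relu_out.forward(out + skip, ctx)
        if self.drop_out is not None:
            out = self.drop_out.forward(out, ctx)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.drop_out is not None:
            grad = self.drop_out.backward(grad)
        grad = self.relu_out.backward(grad)
        dmain = self.main.backward(grad)
        dskip = self.downsample.backward(grad) if self.downsample is not None else grad
        return dmain + dskip


def _maybe_dropout(layers: list[Module], rate: float, enabled: bool) -> None:
    if enabled and rate > 0:
        layers.append(Dropout(rate))


class BasicBlock(_ResidualBlock):
    """Two 3x3 convolutions; expansion 1."""

    expansion = 1

    def __init__(
        self,
        in_ch: int,
        ch: int,
        stride: int,
        dropout_rate: float,
        dropout_in_blocks: bool,
        rng: np.random.Generator,
        dtype=np.float32,
    ):
        super().__init__()
        layers: list[Module] = [
            Conv2d(in_ch, ch, 3, stride=stride, rng=rng, dtype=dtype),
            BatchNorm2d(ch, dtype=dtype),
            ReLU(),
        ]
        _maybe_dropout(layers, dropout_rate, dropout_in_blocks)
        layers += [Conv2d(ch, ch, 3, rng=rng, dtype=dtype), BatchNorm2d(ch, dtype=dtype)]
        self.main = self.register("main", Sequential(*layers))
        if stride != 1 or in_ch != ch:
            self.downsample = self.register(
                "downsample",
                Sequential(
                    Conv2d(in_ch, ch, 1, stride=stride, pad=0, rng=rng, dtype=dtype),
                    BatchNorm2d(ch, dtype=dtype),
                ),
            )
        self.register("relu_out", self.relu_out)
        if dropout_in_blocks and dropout_rate > 0:
            self.drop_out = self.register("drop_out", Dropout(dropout_rate))


class Bottleneck(_ResidualBlock):
    """1x1 -> 3x3 -> 1x1 convolutions; expansion 4."""

    expansion = 4

    def __init__(
        self,
        in_ch: int,
        ch: int,
        stride: int,
        dropout_rate: float,
        dropout_in_blocks: bool,
        rng: np.random.Generator,
        dtype=np.float32,
    ):
        super().__init__()
        out_ch = ch * self.expansion
        layers: list[Module] = [
            Conv2d(in_ch, ch, 1, pad=0, rng=rng, dtype=dtype),
            BatchNorm2d(ch, dtype=dtype),
            ReLU(),
        ]
        _maybe_dropout(layers, dropout_rate, dropout_in_blocks)
        layers += [
            Conv2d(ch, ch, 3, stride=stride, rng=rng, dtype=dtype),
            BatchNorm2d(ch, dtype=dtype),
            ReLU(),
        ]
        _maybe_dropout(layers, dropout_rate, dropout_in_blocks)
        layers += [
            Conv2d(ch, out_ch, 1, pad=0, rng=rng, dtype=dtype),
            BatchNorm2d(out_ch, dtype=dtype),
        ]
        self.main = self.register("main", Sequential(*layers))
        if stride != 1 or in_ch != out_ch:
            self.downsample = self.register(
                "downsample",
                Sequential(
                    Conv2d(in_ch, out_ch, 1, stride=stride, pad=0, rng=rng, dtype=dtype),
                    BatchNorm2d(out_ch, dtype=dtype),
                ),
            )
        self.register("relu_out", self.relu_out)
        if dropout_in_blocks and dropout_rate > 0:
            self.drop_out = self.register("drop_out", Dropout(dropout_rate))


class ResNet(Module):
    """Backbone + global average pool + dropout + linear head (one logit)."""

    def __init__(
        self,
        block_cls: type,
        stage_blocks: list[int],
        stage_widths: list[int],
        stem_width: int,
        in_channels: int,
        input_pool: tuple[int, int] | None,
        dropout_rate: float,
        dropout_in_blocks: bool,
        stem_kind: str,
        rng: np.random.Generator,
        dtype=np.float32,
    ):
        super().__init__()
        pre: list[Module] = []
        if input_pool is not None and input_pool != (1, 1):
            pre.append(AvgPool2d(*input_pool))
        if stem_kind == "deep":
            pre += [
                Conv2d(in_channels, stem_width, 7, stride=2, pad=3, rng=rng, dtype=dtype),
                BatchNorm2d(stem_width, dtype=dtype),
                ReLU(),
                MaxPool2d(3, stride=2, pad=1),
            ]
        else:
            pre += [
                Conv2d(in_channels, stem_width, 3, rng=rng, dtype=dtype),
                BatchNorm2d(stem_width, dtype=dtype),
                ReLU(),
                AvgPool2d(2, 2),
            ]
        self.stem = self.register("stem", Sequential(*pre))

        blocks: list[Module] = []
        in_ch = stem_width
        for stage, (n_blocks, width) in enumerate(zip(stage_blocks, stage_widths)):
            for b in range(n_blocks):
                stride = 2 if (b == 0 and stage > 0) else 1
                block = block_cls(
                    in_ch, width, stride, dropout_rate, dropout_in_blocks, rng, dtype
                )
                blocks.append(block)
                in_ch = width * block_cls.expansion
        self.trunk = self.register("trunk", Sequential(*blocks))
        self.pool = self.register("pool", GlobalAvgPool2d())
        self.head_dropout = self.register("head_dropout", Dropout(dropout_rate))
        self.fc = self.register("fc", Linear(in_ch, 1, rng=rng, dtype=dtype))
        self.feature_dim = in_ch

    def forward(self, x: np.ndarray, ctx: Context) -> np.ndarray:
        h = self.stem.forward(x, ctx)
        h = self.trunk.forward(h, ctx)
        h = self.pool.forward(h, ctx)
        h = self.head_dropout.forward(h, ctx)
        return self.fc.forward(h, ctx)[:, 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.fc.backward(grad[:, None])
        g = self.head_dropout.backward(g)
        g = self.pool.backward(g)
        g = self.trunk.backward(g)
        return self.stem.backward(g)

    def dropout_modules(self) -> list[Dropout]:
        return [m for m in self.modules() if isinstance(m, Dropout)]


def make_resnet(
    backbone: str,
    *,
    in_channels: int = 1,
    input_pool: tuple[int, int] | None = None,
    dropout_rate: float = 0.2,
    dropout_in_blocks: bool = True,
    lite_width: int = 8,
    seed: int = 0,
    dtype=np.float32,
) -> ResNet:
    """Construct a backbone by name (``resnet50`` or ``resnet18_lite``)."""
    rng = np.random.default_rng(seed)
    if backbone == "resnet50":
        return ResNet(
            Bottleneck,
            stage_blocks=[3, 4, 6, 3],
            stage_widths=[64, 128, 256, 512],
            stem_width=64,
            in_channels=in_channels,
            input_pool=input_pool,
            dropout_rate=dropout_rate,
            dropout_in_blocks=dropout_in_blocks,
            stem_kind="deep",
            rng=rng,
            dtype=dtype,
        )
    if backbone in ("resnet18_lite", "resnet18-lite"):
        w = lite_width
        return ResNet(
            BasicBlock,
            stage_blocks=[1, 1, 1],
            stage_widths=[w, 2 * w, 4 * w],
            stem_width=w,
            in_channels=in_channels,
            input_pool=input_pool,
            dropout_rate=dropout_rate,
            dropout_in_blocks=dropout_in_blocks,
            stem_kind="lite",
            rng=rng,
            dtype=dtype,
        )
    raise ValueError(f"unknown backbone {backbone!r}")
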