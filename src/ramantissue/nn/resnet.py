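"""1-D residual network for spectrum classification.

The architecture: a stem (convolution -> batch norm -> ReLU -> max pool)
followed by four layers of two residual blocks each, adaptive average
pooling to one position per channel, and a fully connected head whose
softmax yields class probabilities over the tissue types.

Two residual block kinds exist. An *identity block* passes its input
unchanged along the shortcut and adds it to the output of its
convolutional stack — it therefore must preserve both length and channel
count (stride 1, equal channels). A *convolutional block* reshapes the
shortcut with an extra 1-tap convolution + batch norm so channel growth
and stride-2 downsampling can still be added to the main path. All
downsampling lives in the convolutional blocks; the default plan doubles
the width (128, 256, 512) and halves the length at the start of layers
2-4, mirroring canonical residual-network practice translated to 1-D.
Kernel sizes (stem 7, blocks 3) are configurable conventions.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .layers import (
    BatchNorm1d,
    Conv1d,
    GlobalAvgPool1d,
    Layer,
    Linear,
    MaxPool1d,
    Param,
    ReLU,
    softmax,
)

__all__ = [
    "BlockSpec",
    "ResNetConfig",
    "ModelSummary",
    "ConfigurationError",
    "IdentityBlock",
    "ConvBlock",
    "ResNet1D",
    "build_model",
    "count_parameters",
    "default_block_plan",
    "reduced_block_plan",
]


class ConfigurationError(ValueError):
    """Raised when a model configuration cannot produce a valid network."""


@dataclass(frozen=True)
class BlockSpec:
    """One residual block: kind ('identity'|'convolutional'), width, stride, kernel."""

    kind: str
    channels: int
    stride: int = 1
    kernel: int = 3

    def __post_init__(self) -> None:
        if self.kind not in ("identity", "convolutional"):
            raise ConfigurationError(f"unknown block kind {self.kind!r}")
        if self.kind == "identity" and self.stride != 1:
            raise ConfigurationError(
                "identity blocks are shape-preserving and must have stride 1"
            )


def default_block_plan() -> Tuple[BlockSpec, ...]:
    """Four layers x two blocks; widths 64/128/256/512, stride 2 at each widening."""
    return (
        BlockSpec("identity", 64),
        BlockSpec("identity", 64),
        BlockSpec("convolutional", 128, stride=2),
        BlockSpec("identity", 128),
        BlockSpec("convolutional", 256, stride=2),
        BlockSpec("identity", 256),
        BlockSpec("convolutional", 512, stride=2),
        BlockSpec("identity", 512),
    )


def reduced_block_plan() -> Tuple[BlockSpec, ...]:
    """A narrow plan for CPU-scale experiments (widths 16/32/64)."""
    return (
        BlockSpec("identity", 16),
        BlockSpec("convolutional", 32, stride=2),
        BlockSpec("identity", 32),
        BlockSpec("convolutional", 64, stride=2),
    )


@dataclass
class ResNetConfig:
    """Architecture hyperparameters.

    ``input_length`` is the number of spectral channels after
    preprocessing (1401 for the 400-1800 cm^-1 fingerprint at 1 cm^-1
    spacing). ``block_plan`` entries must use convolutional blocks exactly
    where channels or stride change.
    """

    input_length: int = 1401
    num_classes: int = 8
    stem_channels: int = 64
    stem_kernel: int = 7
    stem_stride: int = 2
    pool_kernel: int = 3
    pool_stride: int = 2
    block_plan: Tuple[BlockSpec, ...] = field(default_factory=default_block_plan)
    seed: int = 0

    def __post_init__(self) -> None:
        self.block_plan = tuple(
            b if isinstance(b, BlockSpec) else BlockSpec(**b) for b in self.block_plan
        )
        if self.num_classes < 2:
            raise ConfigurationError("need at least two classes")
        channels = self.stem_channels
        for i, blk in enumerate(self.block_plan):
            if blk.kind == "identity" and blk.channels != channels:
                raise ConfigurationError(
                    f"block {i}: identity block cannot change channels "
                    f"({channels} -> {blk.channels}); use a convolutional block"
                )
            channels = blk.channels

    def to_dict(self) -> dict:
        return {
            "input_length": self.input_length,
            "num_classes": self.num_classes,
            "stem_channels": self.stem_channels,
            "stem_kernel": self.stem_kernel,
            "stem_stride": self.stem_stride,
            "pool_kernel": self.pool_kernel,
            "pool_stride": self.pool_stride,
            "block_plan": [
                {"kind": b.kind, "channels": b.channels, "stride": b.stride,
                 "kernel": b.kernel}
                for b in self.block_plan
            ],
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ResNetConfig":
        d = dict(d)
        if "block_plan" in d:
            d["block_plan"] = tuple(BlockSpec(**b) for b in d["block_plan"])
        return cls(**d)


@dataclass
class ModelSummary:
    """Parameter count plus the (name, output length, channels) chain."""

    parameter_count: int
    layer_shapes: List[Tuple[str, int, int]]


class _ResidualBlock(Layer):
    """Common residual machinery: y = relu(main(x) + shortcut(x))."""

    def __init__(self) -> None:
        self.main: List[Layer] = []
        self.shortcut: List[Layer] = []
        self._relu_mask = None

    def params(self) -> List[Param]:
        out: List[Param] = []
        for layer in self.main + self.shortcut:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = x
        for layer in self.main:
            h = layer.forward(h, training=training)
        s = x
        for layer in self.shortcut:
            s = layer.forward(s, training=training)
        if h.shape != s.shape:
            raise ConfigurationError(
                f"residual addition shape mismatch: main {h.shape} vs "
                f"shortcut {s.shape}"
            )
        y = h + s
        out = np.maximum(y, 0.0)
        if training:
            self._relu_mask = y > 0
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = dy * self._relu_mask
        self._relu_mask = None
        dh = dy
        for layer in reversed(self.main):
            dh = layer.backward(dh)
        ds = dy
        for layer in reversed(self.shortcut):
            ds = layer.backward(ds)
        return dh + ds


class IdentityBlock(_ResidualBlock):
    """Shortcut is the unmodified input; shape-preserving by construction."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator,
                 name: str = "id"):
        super().__init__()
        self.channels = channels
        self.main = [
            Conv1d(channels, channels, kernel, stride=1, rng=rng, name=f"{name}.conv1"),
            BatchNorm1d(channels, name=f"{name}.bn1"),
            ReLU(),
            Conv1d(channels, channels, kernel, stride=1, rng=rng, name=f"{name}.conv2"),
            BatchNorm1d(channels, name=f"{name}.bn2"),
        ]
        self.shortcut = []


class ConvBlock(_ResidualBlock):
    """Shortcut carries a 1-tap convolution + batch norm to match shapes."""

    def __init__(self, in_channels: int, channels: int, kernel: int, stride: int,
                 rng: np.random.Generator, name: str = "conv"):
        super().__init__()
        self.channels = channels
        self.stride = stride
        self.main = [
            Conv1d(in_channels, channels, kernel, stride=stride, rng=rng,
                   name=f"{name}.conv1"),
            BatchNorm1d(channels, name=f"{name}.bn1"),
            ReLU(),
            Conv1d(channels, channels, kernel, stride=1, rng=rng,
                   name=f"{name}.conv2"),
            BatchNorm1d(channels, name=f"{name}.bn2"),
        ]
        self.shortcut = [
            Conv1d(in_channels, channels, 1, stride=stride, rng=rng,
                   name=f"{name}.shortcut"),
            BatchNorm1d(channels, name=f"{name}.shortcut_bn"),
        ]


class ResNet1D:
    """The assembled network. ``forward`` yields logits; ``predict_proba`` applies softmax."""

    def __init__(self, cfg: ResNetConfig):
        self.cfg = cfg
        self.summary = summarize(cfg)  # validates lengths; raises ConfigurationError
        rng = np.random.default_rng(cfg.seed)
        self.stem: List[Layer] = [
            Conv1d(1, cfg.stem_channels, cfg.stem_kernel, stride=cfg.stem_stride,
                   rng=rng, name="stem.conv"),
            BatchNorm1d(cfg.stem_channels, name="stem.bn"),
            ReLU(),
            MaxPool1d(cfg.pool_kernel, cfg.pool_stride, cfg.pool_kernel // 2),
        ]
        self.blocks: List[_ResidualBlock] = []
        channels = cfg.stem_channels
        for i, blk in enumerate(cfg.block_plan):
            if blk.kind == "identity":
                self.blocks.append(IdentityBlock(channels, blk.kernel, rng,
                                                 name=f"block{i}"))
            else:
                self.blocks.append(ConvBlock(channels, blk.channels, blk.kernel,
                                             blk.stride, rng, name=f"block{i}"))
            channels = blk.channels
        self.pool = GlobalAvgPool1d()
        self.fc = Linear(channels, cfg.num_classes, rng=rng, name="fc")

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> List[Param]:
        out: List[Param] = []
        for layer in self.stem:
            out.extend(layer.params())
        for blk in self.blocks:
            out.extend(blk.params())
        out.extend(self.pool.params())
        out.extend(self.fc.params())
        return out

    def _bn_layers(self) -> List[BatchNorm1d]:
        found = []
        for layer in self.stem:
            if isinstance(layer, BatchNorm1d):
                found.append(layer)
        for blk in self.blocks:
            for layer in blk.main + blk.shortcut:
                if isinstance(layer, BatchNorm1d):
                    found.append(layer)
        return found

    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.params()}
        for i, bn in enumerate(self._bn_layers()):
            state[f"__running_mean_{i}"] = bn.running_mean.copy()
            state[f"__running_var_{i}"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value = state[p.name].copy()
        for i, bn in enumerate(self._bn_layers()):
            bn.running_mean = state[f"__running_mean_{i}"].copy()
            bn.running_var = state[f"__running_var_{i}"].copy()

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    # -- computation --------------------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.ndim == 2:
            x = x[:, None, :]
        if x.shape[2] != self.cfg.input_length:
            raise ValueError(
                f"expected spectra of length {self.cfg.input_length}, "
                f"got {x.shape[2]}"
            )
        if not np.all(np.isfinite(x)):
            raise ValueError("input contains non-finite values")
        return x

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Pre-softmax scores, shape (batch, num_classes)."""
        x = self._check_input(x)
        for layer in self.stem:
            x = layer.forward(x, training=training)
        for blk in self.blocks:
            x = blk.forward(x, training=training)
        x = self.pool.forward(x, training=training)
        return self.fc.forward(x, training=training)

    def backward(self, dlogits: np.ndarray) -> None:
        dy = self.fc.backward(dlogits)
        dy = self.pool.backward(dy)
        for blk in reversed(self.blocks):
            dy = blk.backward(dy)
        for layer in reversed(self.stem):
            dy = layer.backward(dy)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class probabilities (rows on the simplex), evaluation mode."""
        x = self._check_input(x)
        out = []
        for start in range(0, x.shape[0], batch_size):
            logits = self.forward(x[start : start + batch_size], training=False)
            out.append(softmax(logits))
        return np.concatenate(out, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return self.predict_proba(x, batch_size=batch_size).argmax(axis=1)


def summarize(cfg: ResNetConfig) -> ModelSummary:
    """Walk the architecture symbolically, validating every stage length."""
    shapes: List[Tuple[str, int, int]] = []
    length = cfg.input_length
    if length < 1:
        raise ConfigurationError("input_length must be >= 1 (stage: input)")

    def conv_len(stage: str, length: int, kernel: int, stride: int) -> int:
        out = (length + 2 * (kernel // 2) - kernel) // stride + 1
        if out < 1:
            raise ConfigurationError(
                f"input too short: stage {stage!r} would output length {out}"
            )
        return out

    count = 0
    channels = cfg.stem_channels
    length = conv_len("stem_conv", length, cfg.stem_kernel, cfg.stem_stride)
    count += 1 * cfg.stem_channels * cfg.stem_kernel + 2 * cfg.stem_channels
    shapes.append(("stem_conv", length, channels))
    length = conv_len("stem_pool", length, cfg.pool_kernel, cfg.pool_stride)
    shapes.append(("stem_pool", length, channels))

    for i, blk in enumerate(cfg.block_plan):
        name = f"block{i}_{blk.kind}"
        if blk.kind == "identity":
            conv_len(name, length, blk.kernel, 1)
            count += 2 * (channels * channels * blk.kernel + 2 * channels)
        else:
            length = conv_len(name, length, blk.kernel, blk.stride)
            count += channels * blk.channels * blk.kernel + 2 * blk.channels
            count += blk.channels * blk.channels * blk.kernel + 2 * blk.channels
            count += channels * blk.channels * 1 + 2 * blk.channels
            channels = blk.channels
        shapes.append((name, length, channels))

    shapes.append(("avgpool", 1, channels))
    count += channels * cfg.num_classes + cfg.num_classes
    shapes.append(("fc", 1, cfg.num_classes))
    return ModelSummary(parameter_count=count, layer_shapes=shapes)


def build_model(cfg: Optional[ResNetConfig] = None) -> ResNet1D:
    """Construct the network from a configuration (default: the full plan)."""
    return ResNet1D(cfg or ResNetConfig())


def count_parameters(model: ResNet1D) -> int:
    """Total trainable scalar parameters (batch-norm running stats excluded)."""
    return sum(p.size for p in model.params())
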