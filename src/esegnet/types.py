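"""Shared lightweight containers."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np


@dataclass
class FeatureMap:
    """A dense feature array in (batch, channels, spatial...) layout with an
    explicit per-axis stride relative to the network input."""

    values: np.ndarray
    stride: Tuple[int, ...]

    def __post_init__(self):
        self.stride = tuple(int(s) for s in self.stride)
        if self.values.ndim != 2 + len(self.stride):
            raise ValueError("stride rank does not match spatial rank")
        if self.values.shape[1] < 1 or any(e < 1 for e in self.values.shape[2:]):
            raise ValueError("channels and spatial extents must be >= 1")
        if any(s < 1 for s in self.stride):
            raise ValueError("stride entries must be positive integers")

    @property
    def channels(self) -> int:
        return self.values.shape[1]

    @property
    def spatial(self) -> Tuple[int, ...]:
        return self.values.shape[2:]


@dataclass(frozen=True)
class EncoderStageSpec:
    """One encoder stage: 1-based index, per-axis stride, channel width."""

    index: int
    stride: Tuple[int, ...]
    channels: int


@dataclass
class StagePyramid:
    """Ordered multi-scale encoder output, one FeatureMap per stage."""

    stages: Sequence[FeatureMap]
    specs: Sequence[EncoderStageSpec]

    def __post_init__(self):
        if len(self.stages) != len(self.specs):
            raise ValueError("stages and specs length mismatch")

    def __len__(self):
        return len(self.stages)

    def stage(self, index: int) -> FeatureMap:
        """Look up a stage by its 1-based index."""
        for fm, sp in zip(self.stages, self.specs):
            if sp.index == index:
                return fm
        raise KeyError(f"no stage with index {index}")

    def validate(self, input_spatial: Tuple[int, ...]) -> None:
        for fm, sp in zip(self.stages, self.specs):
            expect = tuple(e // s for e, s in zip(input_spatial, sp.stride))
            if fm.spatial != expect:
                raise ValueError(
                    f"stage {sp.index}: spatial {fm.spatial} does not match "
                    f"input {input_spatial} / stride {sp.stride}")
            if fm.channels != sp.channels:
                raise ValueError(
                    f"stage {sp.index}: {fm.channels} channels, spec says "
                    f"{sp.channels}")


_BLOCK_KINDS = ("gconv", "dconv", "upconv", "mlkconv", "doubleconv",
                "se_basicconv")


@dataclass(frozen=True)
class BlockSpec:
    """Hyperparameters of a single convolutional block."""

    kind: str
    in_channels: int
    out_channels: int
    kernel: int = 3
    dilation: int = 1
    dim: int = 2

    def __post_init__(self):
        if self.kind not in _BLOCK_KINDS:
            raise ValueError(f"unknown block kind {self.kind!r}")
        if self.dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")
        if self.kernel % 2 == 0:
            raise ValueError("kernel must be odd")
        if self.dilation < 1:
            raise ValueError("dilation must be >= 1")
        if self.kind == "mlkconv":
            if self.in_channels != self.out_channels:
                raise ValueError("mlkconv preserves channels")
            if self.in_channels % 4:
                raise ValueError("mlkconv channels must be divisible by 4")
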