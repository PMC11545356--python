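"""Residual backbone and feature pyramid network.

The backbone exposes its last three stages (strides 4/8/16 relative to the
input) to the FPN.  Two profiles are provided: ``tiny`` — three stages of
one residual block each with 16/32/64 channels, the default for tests and
desk-scale experiments — and ``full``, which mirrors the stage layout of a
deep residual classifier (loading published pretrained weights is out of
scope; depth is configurable instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nnkit
from .nnkit import (
    BatchNorm2d, Conv2d, ConvBNReLU, Module, ResidualBlock, Tensor,
    upsample_nearest2x,
)

__all__ = ["BackboneConfig", "PyramidFeatures", "Backbone", "FPN", "build_fpn"]


@dataclass
class BackboneConfig:
    """Stage widths/depths of the feature extractor.

    ``stage_channels`` and ``stage_blocks`` must list at least three stages
    (the FPN consumes three levels) with non-decreasing channel counts.
    """

    profile: str = "tiny"
    stage_channels: tuple[int, ...] = (16, 32, 64)
    stage_blocks: tuple[int, ...] = (1, 1, 1)

    def __post_init__(self):
        if len(self.stage_channels) < 3:
            raise ValueError("backbone needs >= 3 stages for the pyramid")
        if len(self.stage_channels) != len(self.stage_blocks):
            raise ValueError("stage_channels and stage_blocks length mismatch")
        if any(b <= a for a, b in zip(self.stage_channels, self.stage_channels[1:]) if b < a):
            raise ValueError("stage channels must be non-decreasing")

    @classmethod
    def tiny(cls) -> "BackboneConfig":
        return cls("tiny", (16, 32, 64), (1, 1, 1))

    @classmethod
    def full(cls) -> "BackboneConfig":
        # mirrors the last three stages of a deep residual classifier
        return cls("full", (128, 256, 512), (4, 6, 3))

    def to_json(self) -> dict:
        return {"profile": self.profile,
                "stage_channels": list(self.stage_channels),
                "stage_blocks": list(self.stage_blocks)}

    @classmethod
    def from_json(cls, obj: dict) -> "BackboneConfig":
        return cls(obj["profile"], tuple(obj["stage_channels"]),
                   tuple(obj["stage_blocks"]))


@dataclass
class PyramidFeatures:
    """Per-level feature maps with equal channel counts, strides increasing."""

    maps: list[Tensor]
    strides: tuple[int, ...]

    def __post_init__(self):
        channels = {m.data.shape[1] for m in self.maps}
        if len(channels) > 1:
            raise ValueError(f"pyramid channel counts differ: {channels}")
        if any(b <= a for a, b in zip(self.strides, self.strides[1:])):
            raise ValueError("pyramid strides must be strictly increasing")

    @property
    def channels(self) -> int:
        return self.maps[0].data.shape[1]


class Backbone(Module):
    """Stem (stride 4) followed by residual stages; returns the stage maps."""

    def __init__(self, config: BackboneConfig, rng: np.random.Generator,
                 in_channels: int = 1):
        super().__init__()
        self.config = config
        c0 = config.stage_channels[0]
        self.stem = nnkit.Sequential(
            ConvBNReLU(in_channels, c0, rng, stride=2),
            ConvBNReLU(c0, c0, rng, stride=2),
        )
        self.stages = []
        cin = c0
        for si, (cout, blocks) in enumerate(zip(config.stage_channels,
                                                config.stage_blocks)):
            layers = []
            for bi in range(blocks):
                stride = 2 if (bi == 0 and si > 0) else 1
                layers.append(ResidualBlock(cin, cout, rng, stride=stride))
                cin = cout
            self.stages.append(nnkit.Sequential(*layers))
        # strides of the emitted maps relative to the input
        self.stage_strides = tuple(4 * 2**i for i in range(len(config.stage_channels)))

    def forward(self, x: Tensor) -> list[Tensor]:
        x = self.stem.forward(x)
        outs = []
        for stage in self.stages:
            x = stage.forward(x)
            outs.append(x)
        return outs[-3:]


class FPN(Module):
    """Top-down feature pyramid merge.

    Per level: a 1x1 lateral projection to ``out_channels``, nearest-neighbor
    2x upsampling of the deeper merged map added elementwise, then a 3x3
    smoothing convolution.  Spatial sizes of adjacent inputs must be in exact
    2x relation.
    """

    def __init__(self, in_channels: list[int], out_channels: int,
                 rng: np.random.Generator):
        super().__init__()
        self.out_channels = out_channels
        self.laterals = [Conv2d(c, out_channels, 1, rng, padding=0)
                         for c in in_channels]
        self.smooths = [Conv2d(out_channels, out_channels, 3, rng)
                        for _ in in_channels]

    def forward(self, stage_maps: list[Tensor]) -> list[Tensor]:
        if len(stage_maps) != len(self.laterals):
            raise ValueError("level count mismatch with FPN configuration")
        for shallow, deep in zip(stage_maps, stage_maps[1:]):
            hs, ws = shallow.data.shape[2:]
            hd, wd = deep.data.shape[2:]
            if (hs, ws) != (2 * hd, 2 * wd):
                raise ValueError(
                    f"adjacent pyramid inputs must be in 2x relation, got "
                    f"{(hs, ws)} vs {(hd, wd)}")
        laterals = [lat.forward(m) for lat, m in zip(self.laterals, stage_maps)]
        merged = [laterals[-1]]
        for lat in reversed(laterals[:-1]):
            merged.append(lat + upsample_nearest2x(merged[-1]))
        merged.reverse()  # shallow -> deep
        return [sm.forward(m) for sm, m in zip(self.smooths, merged)]


def build_fpn(stage_maps: list[Tensor], fpn: FPN,
              strides: tuple[int, ...]) -> PyramidFeatures:
    """Run the FPN over backbone stage maps and wrap as PyramidFeatures."""
    if len(stage_maps) < 1:
        raise ValueError("at least one stage map is required")
    return PyramidFeatures(fpn.forward(stage_maps), strides)
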