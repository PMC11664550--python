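"""GrowthNet: the lightweight inverted-bottleneck backbone.

A 3x3 stride-2 stem convolution is followed by four stages of Universal
Inverted Bottleneck (UIB) blocks — pointwise expand, depthwise spatial,
pointwise project, each followed by batch normalization with ReLU after the
first two — downsampling by 2 per stage.  The stages reaching strides 8, 16
and 32 are tapped as the P3/P4/P5 pyramid levels.  There is no fully
connected head; a global-average-pool utility exists for feature probing
but is not on the detection path.

Stage depths and expansion factors are configuration; the repo freezes a
calibrated schedule (see ``configs/``) whose audited complexity matches the
published model size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._tensor import Tensor
from .layers import ConvBNReLU, ConvSpec, Module, global_avg_pool

__all__ = ["UIBSpec", "UIBBlock", "StageConfig", "BackboneConfig",
           "GrowthNet", "PyramidFeatures"]


@dataclass(frozen=True)
class UIBSpec:
    """One Universal Inverted Bottleneck block."""

    c_in: int
    c_out: int
    expansion: float = 4.0
    dw_kernel: int = 3
    stride: int = 1
    use_shortcut: bool = False

    def __post_init__(self):
        if self.dw_kernel not in (3, 5):
            raise ValueError("depthwise kernel must be 3 or 5")
        if self.use_shortcut and not (self.stride == 1 and self.c_in == self.c_out):
            raise ValueError("shortcut requires stride 1 and c_in == c_out")

    @property
    def c_mid(self) -> int:
        return max(1, int(round(self.c_in * self.expansion)))


class UIBBlock(Module):
    """expand(1x1) -> BN -> ReLU -> depthwise -> BN -> ReLU -> project(1x1) -> BN."""

    def __init__(self, spec: UIBSpec, rng: np.random.Generator, name: str = "uib"):
        self.spec = spec
        cm = spec.c_mid
        self.expand = ConvBNReLU(spec.c_in, cm, 1, 1, rng, name=f"{name}.expand")
        self.dw = ConvBNReLU(cm, cm, spec.dw_kernel, spec.stride, rng,
                             groups=cm, name=f"{name}.dw")
        self.project = ConvBNReLU(cm, spec.c_out, 1, 1, rng, act=False,
                                  name=f"{name}.project")

    def forward(self, x: Tensor) -> Tensor:
        y = self.project(self.dw(self.expand(x)))
        return y + x if self.spec.use_shortcut else y

    def audit_records(self, h: int, w: int):
        recs, h, w = self.expand.audit_records(h, w)
        for sub in (self.dw, self.project):
            r, h, w = sub.audit_records(h, w)
            recs += r
        return recs, h, w


@dataclass(frozen=True)
class StageConfig:
    width: int
    depth: int = 1
    expansion: float = 4.0
    repeat_expansion: float | None = None   # expansion of the non-strided repeats
    dw_kernel: int = 3


@dataclass(frozen=True)
class BackboneConfig:
    stem_width: int = 32
    stages: tuple[StageConfig, ...] = (
        StageConfig(128, 1, 4.0, dw_kernel=3),
        StageConfig(256, 1, 4.0, dw_kernel=3),
        StageConfig(512, 2, 2.0, dw_kernel=5),
        StageConfig(1024, 1, 2.0, dw_kernel=5),
    )

    @staticmethod
    def from_dict(d: dict) -> "BackboneConfig":
        stages = tuple(StageConfig(**s) for s in d["stages"])
        return BackboneConfig(stem_width=d.get("stem_width", 32), stages=stages)

    def to_dict(self) -> dict:
        return {"stem_width": self.stem_width,
                "stages": [{"width": s.width, "depth": s.depth,
                            "expansion": s.expansion,
                            "repeat_expansion": s.repeat_expansion,
                            "dw_kernel": s.dw_kernel} for s in self.stages]}


class GrowthNet(Module):
    """Stem + four UIB stages, emitting P3/P4/P5 at strides 8/16/32."""

    def __init__(self, config: BackboneConfig, rng: np.random.Generator):
        self.config = config
        self.stem = ConvBNReLU(3, config.stem_width, 3, 2, rng, name="stem")
        self.stages: list[list[UIBBlock]] = []
        c = config.stem_width
        for si, sc in enumerate(config.stages):
            blocks = [UIBBlock(UIBSpec(c, sc.width, sc.expansion, sc.dw_kernel,
                                       stride=2), rng, name=f"s{si}.b0")]
            rep_e = sc.repeat_expansion if sc.repeat_expansion is not None else sc.expansion
            for bi in range(1, sc.depth):
                blocks.append(UIBBlock(
                    UIBSpec(sc.width, sc.width, rep_e, sc.dw_kernel,
                            stride=1, use_shortcut=True), rng, name=f"s{si}.b{bi}"))
            self.stages.append(blocks)
            c = sc.width
        # channel widths of the tapped pyramid levels
        self.out_channels = tuple(config.stages[i].width for i in (1, 2, 3))

    def forward(self, x: Tensor) -> "PyramidFeatures":
        n, c, h, w = x.shape
        if h % 32 or w % 32:
            raise ValueError("input spatial dims must be divisible by 32")
        y = self.stem(x)
        taps = []
        for blocks in self.stages:
            for blk in blocks:
                y = blk(y)
            taps.append(y)
        return PyramidFeatures(p3=taps[1], p4=taps[2], p5=taps[3])

    def pooled_features(self, x: Tensor) -> Tensor:
        """Global-average-pooled deepest features (utility head, off the
        detection path)."""
        return global_avg_pool(self.forward(x).p5)

    def audit_records(self, h: int, w: int):
        recs, h, w = self.stem.audit_records(h, w)
        for blocks in self.stages:
            for blk in blocks:
                r, h, w = blk.audit_records(h, w)
                recs += r
        return recs, h, w

    def conv_layer_counts(self) -> dict:
        """Two counting conventions for 'number of conv layers'.

        ``blocks`` counts the stem plus each UIB as one unit; ``convs``
        counts every convolution (pointwise and depthwise separately).
        """
        n_blocks = 1 + sum(len(b) for b in self.stages)
        n_convs = 1 + 3 * sum(len(b) for b in self.stages)
        return {"blocks": n_blocks, "convs": n_convs}


@dataclass
class PyramidFeatures:
    """The three pyramid levels at strides 8/16/32."""

    p3: Tensor
    p4: Tensor
    p5: Tensor
    strides: tuple[int, int, int] = (8, 16, 32)

    def as_tuple(self):
        return (self.p3, self.p4, self.p5)
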