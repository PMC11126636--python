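"""Top-down feature-pyramid fusion.

Each extractor output is projected to a common channel width by a 1x1
lateral convolution; starting from the coarsest level the maps are merged
top-down by bilinear upsampling and element-wise addition:

    P4 = lateral(F4)
    Pi = lateral(Fi) + upsample(P_{i+1})   for i = 3, 2, 1

Upsampling uses the half-pixel (align_corners=false) bilinear convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from . import nn
from .nn import autograd as ag
from .backbone import FeaturePyramid


class FusedPyramid(NamedTuple):
    p1: "nn.Tensor"
    p2: "nn.Tensor"
    p3: "nn.Tensor"
    p4: "nn.Tensor"


@dataclass
class FusionConfig:
    d: int = 256                 # common channel width of the fused maps
    post_smooth: bool = False    # optional 3x3 smoothing conv after merging

    def __post_init__(self):
        if self.d < 1:
            raise ValueError("fusion width d must be positive")


class FeaturePyramidFusion(nn.Module):
    def __init__(self, in_channels: tuple[int, int, int, int],
                 cfg: FusionConfig | None = None):
        super().__init__()
        self.cfg = cfg or FusionConfig()
        d = self.cfg.d
        self.lateral1 = nn.Conv2d(in_channels[0], d, 1, bias=True)
        self.lateral2 = nn.Conv2d(in_channels[1], d, 1, bias=True)
        self.lateral3 = nn.Conv2d(in_channels[2], d, 1, bias=True)
        self.lateral4 = nn.Conv2d(in_channels[3], d, 1, bias=True)
        if self.cfg.post_smooth:
            for i in range(1, 5):
                setattr(self, f"smooth{i}", nn.Conv2d(d, d, 3, padding=1, bias=True))

    def _laterals(self):
        return [self.lateral1, self.lateral2, self.lateral3, self.lateral4]

    def forward(self, pyramid: FeaturePyramid) -> FusedPyramid:
        return self.top_down_merge(pyramid)

    def top_down_merge(self, pyramid: FeaturePyramid) -> FusedPyramid:
        maps = list(pyramid)
        for fine, coarse in zip(maps[:-1], maps[1:]):
            fh, ch = fine.shape[2], coarse.shape[2]
            fw, cw = fine.shape[3], coarse.shape[3]
            if (fh + 1) // 2 != ch or (fw + 1) // 2 != cw:
                raise ValueError(
                    f"adjacent pyramid levels must differ by a factor of 2, "
                    f"got {fh}x{fw} vs {ch}x{cw}")
        laterals = [lat(f) for lat, f in zip(self._laterals(), maps)]
        merged = [None] * 4
        merged[3] = laterals[3]
        for i in (2, 1, 0):
            up = ag.upsample_bilinear(merged[i + 1],
                                      maps[i].shape[2], maps[i].shape[3])
            merged[i] = ag.add(laterals[i], up)
        if self.cfg.post_smooth:
            merged = [getattr(self, f"smooth{i + 1}")(m)
                      for i, m in enumerate(merged)]
        return FusedPyramid(*merged)


def lateral_reduce(fusion: FeaturePyramidFusion, level: int, fmap):
    """Apply the 1x1 lateral projection of one pyramid level (1-based)."""
    if not 1 <= level <= 4:
        raise ValueError("level must be in 1..4")
    return fusion._laterals()[level - 1](fmap)
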