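"""Bottleneck residual feature extractor with pluggable attention.

The extractor is a 50-layer-style bottleneck network: a 7x7/2 stem
convolution, a 3x3/2 max pool, then four stages of 1x1-3x3-1x1 residual
blocks with an attention module inserted after the 3x3 convolution of
every block.  It emits the four multi-scale feature maps F1..F4 used by
the fusion stage and the multi-branch classifier.

Attention variants
------------------
``ca``    coordinate attention: per-channel average pooling along the two
          spatial directions, a shared squeeze convolution, and two
          direction-aware sigmoid gate maps.  The default.
``se``    squeeze-and-excitation channel gates (ablation variant).
``cbam``  channel gates (avg+max pooled) followed by a 7x7 spatial gate
          (ablation variant).
``none``  plain residual blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from . import nn
from .nn import autograd as ag
from .nn.autograd import Tensor


class FeaturePyramid(NamedTuple):
    """Outputs of the four extractor stages (coarse last)."""
    f1: Tensor
    f2: Tensor
    f3: Tensor
    f4: Tensor


@dataclass
class AttentionConfig:
    """Configuration of the attention block inserted in each bottleneck.

    The coordinate-attention defaults (reduction 32, hidden floor 8,
    biased 1x1 convolutions, batch-norm on the squeezed representation)
    are the configuration whose parameter count matches the published
    accounting of the architecture; they should not normally be changed.
    """

    variant: str = "ca"
    reduction: int = 32
    min_hidden: int = 8
    conv_bias: bool = True

    def __post_init__(self):
        if self.variant not in ("ca", "se", "cbam", "none"):
            raise ValueError(f"unknown attention variant {self.variant!r}")
        if self.reduction < 1 or self.min_hidden < 1:
            raise ValueError("reduction and min_hidden must be positive")

    @classmethod
    def for_variant(cls, variant: str) -> "AttentionConfig":
        if variant == "ca":
            return cls("ca", reduction=32, min_hidden=8, conv_bias=True)
        if variant in ("se", "cbam"):
            # reduction 4 on the bottleneck mid-channels, bias-free bottleneck
            return cls(variant, reduction=4, min_hidden=1, conv_bias=False)
        return cls("none")


def _check_attention_input(x: Tensor) -> None:
    if x.ndim != 4 or x.shape[1] < 1:
        raise ValueError(f"expected NCHW input with >=1 channel, got {x.shape}")
    if not np.all(np.isfinite(x.data)):
        raise ValueError("attention input contains non-finite values")


class CoordinateAttention(nn.Module):
    """Direction-aware gating: H- and W-pooled descriptors share a squeeze
    conv, then two 1x1 convs produce per-row and per-column sigmoid gates
    which are both multiplied into the input."""

    def __init__(self, channels: int, cfg: AttentionConfig | None = None):
        super().__init__()
        cfg = cfg or AttentionConfig.for_variant("ca")
        if cfg.variant != "ca":
            raise ValueError("CoordinateAttention requires variant 'ca'")
        if channels < 1:
            raise ValueError("channel count must be positive")
        self.channels = channels
        hidden = max(cfg.min_hidden, channels // cfg.reduction)
        self.conv_in = nn.Conv2d(channels, hidden, 1, bias=cfg.conv_bias)
        self.bn = nn.BatchNorm2d(hidden)
        self.conv_h = nn.Conv2d(hidden, channels, 1, bias=cfg.conv_bias)
        self.conv_w = nn.Conv2d(hidden, channels, 1, bias=cfg.conv_bias)

    def forward(self, x):
        _check_attention_input(x)
        n, c, h, w = x.shape
        pool_h = ag.tmean(x, axis=3, keepdims=True)              # N,C,H,1
        pool_w = ag.tmean(x, axis=2, keepdims=True)              # N,C,1,W
        pool_w = ag.transpose(pool_w, (0, 1, 3, 2))              # N,C,W,1
        y = ag.concat([pool_h, pool_w], axis=2)                  # N,C,H+W,1
        y = ag.relu(self.bn(self.conv_in(y)))
        a_h = y[:, :, :h, :]                                     # N,hid,H,1
        a_w = ag.transpose(y[:, :, h:, :], (0, 1, 3, 2))         # N,hid,1,W
        g_h = ag.sigmoid(self.conv_h(a_h))
        g_w = ag.sigmoid(self.conv_w(a_w))
        return ag.mul(ag.mul(x, g_h), g_w)


class SEAttention(nn.Module):
    """Squeeze-and-excitation: global average pool, two-layer bottleneck,
    per-channel sigmoid gates."""

    def __init__(self, channels: int, cfg: AttentionConfig | None = None):
        super().__init__()
        cfg = cfg or AttentionConfig.for_variant("se")
        if channels < 1:
            raise ValueError("channel count must be positive")
        hidden = max(cfg.min_hidden, channels // cfg.reduction)
        self.fc1 = nn.Linear(channels, hidden, bias=cfg.conv_bias)
        self.fc2 = nn.Linear(hidden, channels, bias=cfg.conv_bias)
        self.channels = channels

    def _gate(self, pooled):
        return ag.sigmoid(self.fc2(ag.relu(self.fc1(pooled))))

    def forward(self, x):
        _check_attention_input(x)
        n, c = x.shape[0], x.shape[1]
        pooled = ag.tmean(x, axis=(2, 3))                        # N,C
        gate = ag.reshape(self._gate(pooled), (n, c, 1, 1))
        return ag.mul(x, gate)


class CBAMAttention(nn.Module):
    """Channel gate from avg+max pooled descriptors through a shared
    bottleneck, then a spatial gate from a biased 7x7 convolution over the
    channelwise average and maximum."""

    def __init__(self, channels: int, cfg: AttentionConfig | None = None):
        super().__init__()
        cfg = cfg or AttentionConfig.for_variant("cbam")
        if channels < 1:
            raise ValueError("channel count must be positive")
        hidden = max(cfg.min_hidden, channels // cfg.reduction)
        self.fc1 = nn.Linear(channels, hidden, bias=cfg.conv_bias)
        self.fc2 = nn.Linear(hidden, channels, bias=cfg.conv_bias)
        self.spatial = nn.Conv2d(2, 1, 7, padding=3, bias=True)
        self.channels = channels

    def forward(self, x):
        _check_attention_input(x)
        n, c = x.shape[0], x.shape[1]
        avg = ag.tmean(x, axis=(2, 3))                           # N,C
        mx = ag.amax(ag.amax(x, axis=3), axis=2)                 # N,C
        shared = lambda v: self.fc2(ag.relu(self.fc1(v)))
        ch_gate = ag.sigmoid(ag.add(shared(avg), shared(mx)))
        x = ag.mul(x, ag.reshape(ch_gate, (n, c, 1, 1)))
        sp_avg = ag.tmean(x, axis=1, keepdims=True)              # N,1,H,W
        sp_max = ag.amax(x, axis=1, keepdims=True)
        sp_gate = ag.sigmoid(self.spatial(ag.concat([sp_avg, sp_max], axis=1)))
        return ag.mul(x, sp_gate)


_ATTENTION = {"ca": CoordinateAttention, "se": SEAttention, "cbam": CBAMAttention}


def build_attention(channels: int, cfg: AttentionConfig) -> nn.Module | None:
    if cfg.variant == "none":
        return None
    return _ATTENTION[cfg.variant](channels, cfg)


@dataclass
class BottleneckSpec:
    in_channels: int
    mid_channels: int
    stride: int = 1
    attention: AttentionConfig = field(default_factory=AttentionConfig)
    expansion: int = 4

    @property
    def out_channels(self) -> int:
        return self.mid_channels * self.expansion


class Bottleneck(nn.Module):
    """1x1 / 3x3(+attention) / 1x1 residual block, H(x) = F(x) + x."""

    def __init__(self, spec: BottleneckSpec):
        super().__init__()
        self.spec = spec
        mid, out = spec.mid_channels, spec.out_channels
        self.conv1 = nn.Conv2d(spec.in_channels, mid, 1, bias=False)
        self.bn1 = nn.BatchNorm2d(mid)
        self.conv2 = nn.Conv2d(mid, mid, 3, stride=spec.stride, padding=1, bias=False)
        self.bn2 = nn.BatchNorm2d(mid)
        attn = build_attention(mid, spec.attention)
        if attn is not None:
            self.attention = attn
        self._has_attention = attn is not None
        self.conv3 = nn.Conv2d(mid, out, 1, bias=False)
        self.bn3 = nn.BatchNorm2d(out)
        if spec.stride != 1 or spec.in_channels != out:
            self.down_conv = nn.Conv2d(spec.in_channels, out, 1,
                                       stride=spec.stride, bias=False)
            self.down_bn = nn.BatchNorm2d(out)
            self._has_projection = True
        else:
            self._has_projection = False

    def forward(self, x):
        if x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"bottleneck expects {self.spec.in_channels} channels, got {x.shape[1]}")
        out = ag.relu(self.bn1(self.conv1(x)))
        out = ag.relu(self.bn2(self.conv2(out)))
        if self._has_attention:
            out = self.attention(out)
        out = self.bn3(self.conv3(out))
        shortcut = self.down_bn(self.down_conv(x)) if self._has_projection else x
        return ag.relu(ag.add(out, shortcut))


#: stage layout of the full-size extractor: (blocks per stage, mid-channels)
FULL_BLOCKS = (3, 4, 6, 3)
FULL_MIDS = (64, 128, 256, 512)
FULL_STEM = 64


class ResNetBackbone(nn.Module):
    """Four-stage bottleneck extractor emitting the feature pyramid.

    Parameters
    ----------
    attention : AttentionConfig
        Attention block inserted after each 3x3 convolution.
    stem_width, mid_channels, blocks
        Width/depth layout.  Defaults give the full-size extractor whose
        stage outputs at 224x224 input are 256x56x56, 512x28x28,
        1024x14x14 and 2048x7x7.  Reduced layouts are used for small
        synthetic experiments.
    """

    def __init__(self, attention: AttentionConfig | None = None,
                 stem_width: int = FULL_STEM,
                 mid_channels: tuple[int, ...] = FULL_MIDS,
                 blocks: tuple[int, ...] = FULL_BLOCKS,
                 in_channels: int = 3):
        super().__init__()
        if len(mid_channels) != 4 or len(blocks) != 4:
            raise ValueError("backbone requires exactly four stages")
        self.attention_cfg = attention or AttentionConfig.for_variant("ca")
        self.stem_conv = nn.Conv2d(in_channels, stem_width, 7, stride=2,
                                   padding=3, bias=False)
        self.stem_bn = nn.BatchNorm2d(stem_width)
        self.out_channels = tuple(m * 4 for m in mid_channels)
        stages = []
        cin = stem_width
        for stage_idx, (mid, n_blocks) in enumerate(zip(mid_channels, blocks)):
            layers = []
            for b in range(n_blocks):
                stride = 2 if (b == 0 and stage_idx > 0) else 1
                layers.append(Bottleneck(BottleneckSpec(
                    cin, mid, stride=stride, attention=self.attention_cfg)))
                cin = mid * 4
            stages.append(nn.Sequential(*layers))
        self.stage1, self.stage2, self.stage3, self.stage4 = stages

    def forward(self, x) -> FeaturePyramid:
        return self.extract_features(x)

    def extract_features(self, x) -> FeaturePyramid:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x))
        if x.ndim != 4:
            raise ValueError(f"expected NCHW image batch, got shape {x.shape}")
        h, w = x.shape[2], x.shape[3]
        if h < 32 or w < 32 or h % 32 or w % 32:
            raise ValueError(
                f"input spatial size {h}x{w} must be >=32 and divisible by 32 "
                "for the full pyramid depth")
        x = ag.relu(self.stem_bn(self.stem_conv(x)))
        x = ag.max_pool2d(x, kernel=3, stride=2, padding=1)
        f1 = self.stage1(x)
        f2 = self.stage2(f1)
        f3 = self.stage3(f2)
        f4 = self.stage4(f3)
        return FeaturePyramid(f1, f2, f3, f4)


def count_parameters(module: nn.Module) -> int:
    """Exact count of trainable scalars in a component."""
    return module.num_parameters()


def count_attention_parameters(backbone: ResNetBackbone) -> int:
    """Total parameters of all attention blocks inserted in the backbone."""
    total = 0
    for m in backbone.modules():
        if isinstance(m, (CoordinateAttention, SEAttention, CBAMAttention)):
            total += m.num_parameters()
    return total
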