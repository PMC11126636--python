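"""Multi-branch feature classifier (MFC).

Each fused pyramid level feeds a class-specific residual attention (CSRA)
head: a bias-free 1x1 convolution projects the C-channel map to one score
map per class, and per-class spatial pooling combines the plain average
score with a softmax-attention-weighted score,

    y^k = (1/hw) sum_i X_i^k  +  lambda * sum_i softmax(T X^k)_i X_i^k ,

where the softmax runs over the h*w spatial positions of class k.  The
four branch logit vectors are combined by a weighted sum and a sigmoid,
y_final = sigma(sum_i w_i y_i).  Branch outputs are treated as logits
throughout; probabilities appear only after the decision fusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from . import nn
from .nn import autograd as ag
from .nn.autograd import Tensor
from .backbone import ResNetBackbone, AttentionConfig, FeaturePyramid
from .fusion import FeaturePyramidFusion, FusionConfig, FusedPyramid

#: per-branch spatial-pooling weights for branches 1..4
DEFAULT_LAMBDAS = (0.5, 0.4, 0.3, 0.1)
DEFAULT_TEMPERATURE = 1.0


def csra_pool(scores, lam: float, temperature: float = DEFAULT_TEMPERATURE):
    """Class-specific residual attention pooling of per-class score maps.

    Parameters
    ----------
    scores : Tensor or array, shape (N, d, h, w) or (d, h, w)
        Per-class spatial scores.
    lam : float
        Non-negative weight of the spatial-attention term.
    temperature : float
        Positive sharpness of the positional softmax.

    Returns
    -------
    Tensor of shape (N, d) (or (d,) for unbatched input) of per-class logits.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    x = scores if isinstance(scores, Tensor) else Tensor(np.asarray(scores))
    unbatched = x.ndim == 3
    if unbatched:
        x = ag.reshape(x, (1,) + x.shape)
    if x.ndim != 4:
        raise ValueError(f"expected (N,d,h,w) score maps, got {x.shape}")
    if not np.all(np.isfinite(x.data)):
        raise ValueError("score maps contain non-finite values")
    n, d, h, w = x.shape
    flat = ag.reshape(x, (n, d, h * w))
    base = ag.tmean(flat, axis=2)
    attn = ag.softmax(flat, axis=2, temperature=temperature)
    spatial = ag.tsum(ag.mul(attn, flat), axis=2)
    out = ag.add(base, ag.mul(spatial, float(lam)))
    return ag.reshape(out, (d,)) if unbatched else out


class CSRAHead(nn.Module):
    """1x1 bias-free score projection followed by CSRA pooling."""

    def __init__(self, in_channels: int, num_classes: int = 14,
                 lam: float = 0.1, temperature: float = DEFAULT_TEMPERATURE):
        super().__init__()
        if temperature <= 0:
            raise ValueError("temperature must be positive")
        if lam < 0:
            raise ValueError("lambda must be non-negative")
        self.num_classes = num_classes
        self.lam = lam
        self.temperature = temperature
        self.projection = nn.Conv2d(in_channels, num_classes, 1, bias=False)

    def score_maps(self, fmap):
        if fmap.shape[1] != self.projection.in_channels:
            raise ValueError(
                f"head expects {self.projection.in_channels} channels, "
                f"got {fmap.shape[1]}")
        return self.projection(fmap)

    def forward(self, fmap):
        return csra_pool(self.score_maps(fmap), self.lam, self.temperature)


class DecisionFusion(nn.Module):
    """Weighted logit sum + sigmoid.  Weights are fixed (uniform 1/4 by
    default) or, optionally, trainable through a softplus map that keeps
    them positive."""

    def __init__(self, weights: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
                 trainable: bool = False):
        super().__init__()
        w = np.asarray(weights, dtype=np.float64)
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("fusion weights must be non-negative, not all zero")
        self.trainable = trainable
        if trainable:
            # inverse softplus so the initial effective weights equal `weights`
            raw = np.log(np.expm1(np.maximum(w, 1e-6)))
            self.raw_weights = nn.Parameter(raw.astype(np.float32))
        else:
            self.register_buffer("fixed_weights", w)

    def effective_weights(self):
        if self.trainable:
            return ag.log(ag.add(ag.exp(self.raw_weights), 1.0))
        return Tensor(self.fixed_weights)

    def forward(self, branch_logits: Sequence):
        lengths = {tuple(b.shape) for b in branch_logits}
        if len(lengths) != 1:
            raise ValueError(f"branch logit shapes differ: {lengths}")
        w = self.effective_weights()
        total = None
        for i, y in enumerate(branch_logits):
            term = ag.mul(y, w[i])
            total = term if total is None else ag.add(total, term)
        return ag.sigmoid(total)


def fuse_decisions(branch_logits: Sequence, weights=(0.25, 0.25, 0.25, 0.25)):
    """Functional form of the weighted sigmoid decision fusion."""
    return DecisionFusion(weights)(branch_logits)


class MBRANetOutput(NamedTuple):
    probabilities: Tensor          # (N, K) sigmoid outputs
    branch_logits: tuple           # four (N, K) logit tensors
    fused: FusedPyramid
    pyramid: FeaturePyramid


@dataclass
class ModelConfig:
    num_classes: int = 14
    attention: str = "ca"
    lambdas: tuple[float, float, float, float] = DEFAULT_LAMBDAS
    temperature: float = DEFAULT_TEMPERATURE
    fusion_width: int = 256
    fusion_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    trainable_fusion_weights: bool = False
    heads_on_raw: bool = False     # ablation: heads on F1..F4 instead of F1'..F4'
    stem_width: int = 64
    mid_channels: tuple[int, int, int, int] = (64, 128, 256, 512)
    blocks: tuple[int, int, int, int] = (3, 4, 6, 3)

    @classmethod
    def reduced(cls, **overrides) -> "ModelConfig":
        """Width/depth-reduced layout for small synthetic experiments."""
        base = dict(stem_width=16, mid_channels=(8, 16, 32, 64),
                    blocks=(2, 2, 2, 2), fusion_width=32)
        base.update(overrides)
        return cls(**base)


class MBRANet(nn.Module):
    """Full model: attention backbone -> pyramid fusion -> four CSRA heads
    -> weighted sigmoid decision fusion."""

    def __init__(self, config: ModelConfig | None = None):
        super().__init__()
        self.config = config or ModelConfig()
        cfg = self.config
        self.backbone = ResNetBackbone(
            attention=AttentionConfig.for_variant(cfg.attention),
            stem_width=cfg.stem_width, mid_channels=cfg.mid_channels,
            blocks=cfg.blocks)
        self.fusion = FeaturePyramidFusion(
            self.backbone.out_channels, FusionConfig(d=cfg.fusion_width))
        head_channels = (self.backbone.out_channels if cfg.heads_on_raw
                         else (cfg.fusion_width,) * 4)
        for i, (c, lam) in enumerate(zip(head_channels, cfg.lambdas), start=1):
            setattr(self, f"head{i}", CSRAHead(
                c, cfg.num_classes, lam=lam, temperature=cfg.temperature))
        self.decision = DecisionFusion(cfg.fusion_weights,
                                       trainable=cfg.trainable_fusion_weights)

    def heads(self):
        return [self.head1, self.head2, self.head3, self.head4]

    def forward(self, images) -> MBRANetOutput:
        pyramid = self.backbone.extract_features(images)
        fused = self.fusion(pyramid)
        sources = pyramid if self.config.heads_on_raw else fused
        logits = tuple(head(fmap) for head, fmap in zip(self.heads(), sources))
        probs = self.decision(logits)
        return MBRANetOutput(probs, logits, fused, pyramid)

    def predict_proba(self, images) -> np.ndarray:
        self.eval()
        return self.forward(images).probabilities.data
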