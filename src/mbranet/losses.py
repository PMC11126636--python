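"""Multi-label binary cross-entropy with label smoothing.

Hard targets y_i in {0,1} are replaced by

    yhat_i = 1 - alpha        if y_i = 1
    yhat_i = alpha / K        if y_i = 0

with smoothing factor alpha (default 0.1) and K classes (default 14); the
loss is the binary cross-entropy against the smoothed targets, averaged
over the K classes and then over the batch.  Predictions are clamped to
[eps, 1-eps] before the logarithms.

Two routes are provided: plain numpy functions returning floats (used in
evaluation and tests) and a differentiable version on the autograd tensor
type (used in training).
"""

from __future__ import annotations

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor

EPS = 1e-7
DEFAULT_ALPHA = 0.1
DEFAULT_K = 14


def smooth_labels(y, alpha: float = DEFAULT_ALPHA, k: int | None = None) -> np.ndarray:
    """Map binary labels to smoothed targets {alpha/K, 1-alpha}."""
    if not 0 <= alpha < 1:
        raise ValueError("smoothing factor alpha must be in [0, 1)")
    y = np.asarray(y, dtype=np.float64)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be binary")
    if k is None:
        k = y.shape[-1]
    if k < 1:
        raise ValueError("K must be at least 1")
    return np.where(y == 1.0, 1.0 - alpha, alpha / k)


def _clamp_np(p: np.ndarray) -> np.ndarray:
    return np.clip(p, EPS, 1.0 - EPS)


def bce(p, y) -> float:
    """Plain multi-label BCE: mean over classes, then over the batch."""
    p = _clamp_np(np.asarray(p, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {y.shape}")
    per = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return float(per.mean(axis=-1).mean())


def bce_with_label_smoothing(p, y, alpha: float = DEFAULT_ALPHA,
                             k: int | None = None) -> float:
    """Label-smoothed multi-label BCE (numpy route)."""
    p = _clamp_np(np.asarray(p, dtype=np.float64))
    yhat = smooth_labels(y, alpha, k)
    if p.shape != yhat.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {yhat.shape}")
    per = -(yhat * np.log(p) + (1.0 - yhat) * np.log(1.0 - p))
    return float(per.mean(axis=-1).mean())


class BCEWithLabelSmoothing:
    """Differentiable label-smoothed BCE over predicted probabilities."""

    def __init__(self, alpha: float = DEFAULT_ALPHA):
        if not 0 <= alpha < 1:
            raise ValueError("smoothing factor alpha must be in [0, 1)")
        self.alpha = alpha

    def __call__(self, probs: Tensor, labels: np.ndarray) -> Tensor:
        yhat = smooth_labels(labels, self.alpha, k=probs.shape[-1])
        yhat = yhat.astype(probs.dtype)
        p = ag.clamp(probs, EPS, 1.0 - EPS)
        pos = ag.mul(ag.log(p), Tensor(yhat))
        neg = ag.mul(ag.log(ag.add(ag.mul(p, -1.0), 1.0)), Tensor(1.0 - yhat))
        per = ag.mul(ag.add(pos, neg), -1.0)
        return ag.tmean(per)


class BCELoss(BCEWithLabelSmoothing):
    """Plain multi-label BCE reference (alpha = 0)."""

    def __init__(self):
        super().__init__(alpha=0.0)
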