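"""Per-class ROC/AUC metrics and Grad-CAM weak localisation.

AUC is the area under the ROC curve (FPR = FP/(FP+TN) against
TPR = TP/(TP+FN) over all score thresholds), equivalent to the
Mann-Whitney pairwise statistic with half credit for ties.  The mean AUC
averages, unweighted, over the classes for which both a positive and a
negative example are present; classes with a single label value are
excluded and reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .nn import autograd as ag
from .nn.autograd import Tensor

logger = logging.getLogger(__name__)


class UndefinedMetricError(ValueError):
    """Raised when a metric needs both classes but only one is present."""


def _check_binary_pair(scores, labels):
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    if labels.min() == labels.max():
        raise UndefinedMetricError(
            "ROC is undefined: only one class present in labels")
    return scores, labels


def roc_points(scores, labels) -> list[tuple[float, float]]:
    """(FPR, TPR) at every distinct threshold, endpoints (0,0) and (1,1)."""
    scores, labels = _check_binary_pair(scores, labels)
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    pts = list(zip(fpr.tolist(), tpr.tolist()))
    if pts[0] != (0.0, 0.0):
        pts.insert(0, (0.0, 0.0))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return pts


def auc(scores, labels) -> float:
    """Area under the ROC curve for one class."""
    scores, labels = _check_binary_pair(scores, labels)
    return float(roc_auc_score(labels, scores))


@dataclass
class MeanAUCResult:
    mean_auc: float
    per_class: np.ndarray        # nan for excluded classes
    evaluated: list[int]
    excluded: list[int]


def mean_auc(scores, labels) -> MeanAUCResult:
    """Unweighted mean per-class AUC over the evaluable classes."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 2:
        raise ValueError("expected matching N x K score and label matrices")
    k = scores.shape[1]
    per = np.full(k, np.nan)
    evaluated, excluded = [], []
    for j in range(k):
        try:
            per[j] = auc(scores[:, j], labels[:, j])
            evaluated.append(j)
        except UndefinedMetricError:
            excluded.append(j)
    if not evaluated:
        raise UndefinedMetricError("no class has both positive and negative labels")
    if excluded:
        logger.info("mean AUC excludes single-label classes: %s", excluded)
    return MeanAUCResult(float(np.nanmean(per)), per, evaluated, excluded)


# ------------------------------------------------------------------ Grad-CAM
@dataclass
class Heatmap:
    values: np.ndarray           # H x W in [0, 1], max 1 unless all-zero
    class_index: int


def grad_cam(model, image, class_index: int, target_layer: str = "backbone") -> Heatmap:
    """Gradient-weighted class activation map for one image.

    ``target_layer`` selects the activation map: ``backbone`` (the final
    extractor stage, the default) or ``fused1``..``fused4`` for the fused
    pyramid levels.
    """
    arr = np.asarray(image, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[None]
    n, _, h, w = arr.shape
    if n != 1:
        raise ValueError("grad_cam expects a single image")
    model.eval()
    model.zero_grad()
    out = model(Tensor(arr))
    k = out.branch_logits[0].shape[-1]
    if not 0 <= class_index < k:
        raise IndexError(f"class index {class_index} out of range for {k} classes")
    if target_layer == "backbone":
        target = out.pyramid.f4
    elif target_layer.startswith("fused"):
        target = out.fused[int(target_layer[-1]) - 1]
    else:
        raise ValueError(f"unknown target layer {target_layer!r}")
    # final pre-sigmoid logit for the class: weighted sum of branch logits
    weights = model.decision.effective_weights()
    logit = None
    for i, y in enumerate(out.branch_logits):
        term = ag.mul(y[0, class_index], weights[i])
        logit = term if logit is None else ag.add(logit, term)
    logit.backward()
    grads = target.grad[0]                       # C x h x w
    acts = target.data[0]
    alpha = grads.mean(axis=(1, 2))              # channel importance
    cam = np.maximum((alpha[:, None, None] * acts).sum(axis=0), 0.0)
    if cam.max() > 0:
        cam = cam / cam.max()
    up = ag.upsample_bilinear(Tensor(cam[None, None].astype(np.float32)), h, w)
    values = np.clip(up.data[0, 0], 0.0, 1.0)
    if values.max() > 0:
        values = values / values.max()
    return Heatmap(values=values, class_index=class_index)


def save_heatmap_overlay(heatmap: Heatmap, image, out_path) -> None:
    """Write the heatmap blended over the (grayscale) image as a PNG."""
    import matplotlib.cm as cm
    from PIL import Image as PILImage

    arr = np.asarray(image, dtype=np.float32)
    if arr.ndim == 3 and arr.shape[0] in (1, 3):
        arr = arr.mean(axis=0)
    arr = (arr - arr.min()) / (np.ptp(arr) + 1e-12)
    color = cm.jet(heatmap.values)[..., :3]
    overlay = 0.5 * np.stack([arr] * 3, axis=-1) + 0.5 * color
    PILImage.fromarray((np.clip(overlay, 0, 1) * 255).astype(np.uint8)).save(out_path)
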