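"""Configuration-driven training, evaluation, and prediction.

The full-scale protocol (the package defaults) is: Adam with learning
rate 1e-4, betas (0.9, 0.999), eps 1e-8, weight decay 1e-5, batch 64, up
to 60 epochs; the learning rate is divided by 10 when the validation
mean AUC has not improved for 5 epochs, and training stops early after 5
epochs without improvement (the early-stopping counter resets on any
improvement, so a recovery after a rate drop extends training).  The
best-by-validation-mean-AUC weights are retained.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from . import nn
from .nn import autograd as ag
from .nn.autograd import Tensor
from .classifier import MBRANet, ModelConfig, DEFAULT_LAMBDAS
from .data import SampleRecord, preprocess, CHESTXRAY14_CLASSES
from .evaluation import mean_auc
from .losses import BCEWithLabelSmoothing, bce_with_label_smoothing

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    betas: tuple[float, float] = (0.9, 0.999)
    eps: float = 1e-8
    batch_size: int = 64
    max_epochs: int = 60
    plateau_patience: int = 5
    plateau_factor: float = 0.1
    early_stop_patience: int = 5
    seed: int = 0
    alpha: float = 0.1
    lambdas: tuple[float, float, float, float] = DEFAULT_LAMBDAS
    attention: str = "ca"
    trainable_fusion_weights: bool = False
    monitor: str = "mean_auc"            # or "loss"
    resize_to: int = 256
    crop_to: int = 224
    model_scale: str = "full"            # "full" or "reduced"
    num_classes: int = 14

    def __post_init__(self):
        if self.monitor not in ("mean_auc", "loss"):
            raise ValueError("monitor must be 'mean_auc' or 'loss'")
        for name in ("learning_rate", "batch_size", "max_epochs", "crop_to"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def scaled_synthetic(cls, seed: int = 0, **overrides) -> "TrainConfig":
        """The scaled-down synthetic protocol: reduced model on 64x64
        motif images, from-scratch Adam (lr 3e-3, batch 16), <=5 epochs."""
        base = dict(model_scale="reduced", learning_rate=3e-3, batch_size=16,
                    max_epochs=5, resize_to=72, crop_to=64, seed=seed)
        base.update(overrides)
        return cls(**base)

    def build_model(self) -> MBRANet:
        nn.seed(self.seed)
        common = dict(num_classes=self.num_classes, attention=self.attention,
                      lambdas=tuple(self.lambdas),
                      trainable_fusion_weights=self.trainable_fusion_weights)
        if self.model_scale == "reduced":
            return MBRANet(ModelConfig.reduced(**common))
        return MBRANet(ModelConfig(**common))


@dataclass
class RunLog:
    config: dict
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_metric: float = float("nan")
    checkpoint_path: str | None = None

    def append(self, **row) -> None:
        self.epochs.append(row)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _load_batch(records: list[SampleRecord], phase: str, rng,
                resize_to: int, crop_to: int):
    images = np.stack([preprocess(r.image_path, phase, rng,
                                  resize_to=resize_to, crop_to=crop_to)
                       for r in records])
    labels = np.stack([r.labels for r in records])
    return images, labels


def save_checkpoint(path, model: MBRANet, config: TrainConfig) -> None:
    """Single-file weights + config echo + library version."""
    state = model.state_dict()
    meta = json.dumps({"config": dataclasses.asdict(config),
                       "version": _pkg_version})
    np.savez(path, __meta__=np.array(meta), **state)


def load_checkpoint(path) -> tuple[MBRANet, TrainConfig]:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k: data[k] for k in data.files if k != "__meta__"}
    cfg_dict = meta["config"]
    for key in ("betas", "lambdas"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = TrainConfig(**cfg_dict)
    model = config.build_model()
    model.load_state_dict(state)
    return model, config


def _epoch_validation(model, records, config, loss_fn):
    probs, labels = predict_records(model, records, config, return_labels=True)
    val_loss = bce_with_label_smoothing(probs, labels, config.alpha)
    result = mean_auc(probs, labels)
    return val_loss, result.mean_auc


def predict_records(model, records, config: TrainConfig, batch_size: int = 32,
                    return_labels: bool = False):
    model.eval()
    chunks = []
    for i in range(0, len(records), batch_size):
        images, _ = _load_batch(records[i:i + batch_size], "eval_deterministic",
                                None, config.resize_to, config.crop_to)
        chunks.append(model(Tensor(images)).probabilities.data)
    probs = np.concatenate(chunks) if chunks else np.zeros((0, config.num_classes))
    if return_labels:
        return probs, np.stack([r.labels for r in records])
    return probs


def train(config: TrainConfig, train_records: list[SampleRecord],
          val_records: list[SampleRecord], checkpoint_path=None,
          model: MBRANet | None = None, progress: bool = False):
    """Train a model; returns (model-with-best-weights, RunLog)."""
    if not train_records:
        raise ValueError("training split is empty")
    model = model if model is not None else config.build_model()
    loss_fn = BCEWithLabelSmoothing(config.alpha)
    optimizer = nn.Adam(model.parameters(), lr=config.learning_rate,
                        betas=config.betas, eps=config.eps,
                        weight_decay=config.weight_decay)
    mode = "max" if config.monitor == "mean_auc" else "min"
    scheduler = nn.ReduceLROnPlateau(optimizer, mode=mode,
                                     factor=config.plateau_factor,
                                     patience=config.plateau_patience)
    stopper = nn.EarlyStopping(mode=mode, patience=config.early_stop_patience)
    rng = np.random.default_rng(config.seed)
    log = RunLog(config=dataclasses.asdict(config))
    best_state = None

    iterator = range(config.max_epochs)
    if progress:
        from tqdm import tqdm
        iterator = tqdm(iterator, desc="epochs")
    for epoch in iterator:
        model.train()
        order = rng.permutation(len(train_records))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [train_records[j] for j in order[start:start + config.batch_size]]
            images, labels = _load_batch(batch, "train", rng,
                                         config.resize_to, config.crop_to)
            out = model(Tensor(images))
            loss = loss_fn(out.probabilities, labels)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, "
                    f"batch starting {start}: {float(loss.data)!r}; "
                    f"lr={optimizer.lr}, batch labels sum={labels.sum()}")
            model.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
        train_loss = float(np.mean(losses))
        val_loss, val_auc = _epoch_validation(model, val_records, config, loss_fn)
        metric = val_auc if config.monitor == "mean_auc" else val_loss
        log.append(epoch=epoch, train_loss=train_loss, val_loss=val_loss,
                   val_mean_auc=val_auc, lr=optimizer.lr)
        logger.info("epoch %d: train %.4f  val %.4f  val mAUC %.4f  lr %.2g",
                    epoch, train_loss, val_loss, val_auc, optimizer.lr)
        improved = (log.best_epoch < 0 or
                    (metric > log.best_metric if mode == "max"
                     else metric < log.best_metric))
        if improved:
            log.best_epoch = epoch
            log.best_metric = metric
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
            if checkpoint_path is not None:
                save_checkpoint(checkpoint_path, model, config)
                log.checkpoint_path = str(checkpoint_path)
        scheduler.step(metric)
        if stopper.step(metric, epoch):
            logger.info("early stopping at epoch %d (best %d)", epoch, log.best_epoch)
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, log


def evaluate(model: MBRANet, records: list[SampleRecord],
             config: TrainConfig, class_names=None) -> pd.DataFrame:
    """Per-class AUC report; one row per class plus a 'Mean' row."""
    if not records:
        raise ValueError("evaluation split is empty")
    k = records[0].labels.shape[0]
    if k != config.num_classes:
        raise ValueError(
            f"class-list mismatch: model expects {config.num_classes}, data has {k}")
    class_names = list(class_names or CHESTXRAY14_CLASSES[:k])
    probs, labels = predict_records(model, records, config, return_labels=True)
    result = mean_auc(probs, labels)
    rows = [{"class": name, "auc": result.per_class[j],
             "evaluated": j in result.evaluated}
            for j, name in enumerate(class_names)]
    rows.append({"class": "Mean", "auc": result.mean_auc, "evaluated": True})
    return pd.DataFrame(rows)


def predict(model: MBRANet, image_paths, config: TrainConfig,
            class_names=None, top: int = 6) -> pd.DataFrame:
    """Per-image class probabilities plus a top-k listing."""
    class_names = list(class_names or CHESTXRAY14_CLASSES[:config.num_classes])
    rows = []
    model.eval()
    for path in image_paths:
        try:
            image = preprocess(path, "eval_deterministic",
                               resize_to=config.resize_to, crop_to=config.crop_to)
        except Exception as exc:                  # unreadable image: skip
            logger.warning("skipping unreadable image %s: %s", path, exc)
            continue
        probs = model(Tensor(image[None])).probabilities.data[0]
        order = np.argsort(-probs)[:top]
        row = {"image": str(path)}
        row.update({name: float(p) for name, p in zip(class_names, probs)})
        row["top_predictions"] = "; ".join(
            f"{class_names[j]}:{probs[j]:.3f}" for j in order)
        rows.append(row)
    return pd.DataFrame(rows)


def count_components(config: TrainConfig) -> dict[str, int]:
    """Parameter accounting per component of a freshly built model."""
    from .backbone import count_attention_parameters
    model = config.build_model()
    attn = count_attention_parameters(model.backbone)
    backbone = model.backbone.num_parameters() - attn
    heads = sum(h.num_parameters() for h in model.heads())
    fusionp = model.fusion.num_parameters()
    decision = model.decision.num_parameters()
    total = model.num_parameters()
    return {"backbone": backbone, "attention": attn, "fusion": fusionp,
            "heads": heads, "decision": decision, "total": total}
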