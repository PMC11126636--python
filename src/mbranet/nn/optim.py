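"""Adam optimiser with decoupled-from-nothing classic L2 weight decay,
plus a reduce-on-plateau learning-rate schedule and early stopping."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data = p.data - self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class ReduceLROnPlateau:
    """Divide the learning rate by ``1/factor`` when the monitored metric
    has not improved for ``patience`` consecutive epochs."""

    def __init__(self, optimizer: Adam, mode: str = "max",
                 factor: float = 0.1, patience: int = 5):
        if mode not in ("max", "min"):
            raise ValueError("mode must be 'max' or 'min'")
        self.optimizer = optimizer
        self.mode = mode
        self.factor = factor
        self.patience = patience
        self.best: float | None = None
        self.bad_epochs = 0
        self.num_reductions = 0

    def _improved(self, metric: float) -> bool:
        if self.best is None:
            return True
        return metric > self.best if self.mode == "max" else metric < self.best

    def step(self, metric: float) -> bool:
        """Returns True if the learning rate was reduced this epoch."""
        if self._improved(metric):
            self.best = metric
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        if self.bad_epochs > self.patience - 1 and self.patience > 0:
            self.optimizer.lr *= self.factor
            self.num_reductions += 1
            self.bad_epochs = 0
            return True
        return False


class EarlyStopping:
    """Stop when the metric has not improved for ``patience`` epochs.
    The counter resets on any improvement, so a post-plateau recovery
    (e.g. after a learning-rate drop) extends training."""

    def __init__(self, mode: str = "max", patience: int = 5):
        self.mode = mode
        self.patience = patience
        self.best: float | None = None
        self.best_epoch = -1
        self.bad_epochs = 0

    def step(self, metric: float, epoch: int) -> bool:
        """Returns True when training should stop."""
        improved = (self.best is None or
                    (metric > self.best if self.mode == "max" else metric < self.best))
        if improved:
            self.best = metric
            self.best_epoch = epoch
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        return self.bad_epochs >= self.patience
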