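"""Training: cross-entropy + weight decay, minimized by seeded
mini-batch SGD with momentum.

The objective is the mean negative log-likelihood of the true labels
under the softmax head plus a weight-decay term lambda/2 * ||W||^2 over
the weight tensors (biases are not decayed).  Updates are classical
momentum: v <- m*v - eta*(grad + lambda*W); theta <- theta + v, with the
learning rate stepped down once at a configured epoch.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass

import numpy as np

from ..datatypes import ParameterError
from . import layers as L
from .model import PatchClassifier

logger = logging.getLogger("octchoroid.cnn")


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule settings.

    The full profile is 40 epochs at learning rate 1e-3 dropping to 1e-4
    at epoch 21, momentum 0.9, weight decay 5e-4, batches of 50.  The
    reduced profile (5 epochs, at most 10k patches) is the desk-scale
    default used by the tests and the worked examples.
    """

    epochs: int = 40
    batch_size: int = 50
    momentum: float = 0.9
    weight_decay: float = 5e-4
    lr: float = 1e-3
    lr_after: float = 1e-4
    lr_drop_epoch: int = 21     # first epoch (1-based) at the lower rate
    holdout_fraction: float = 0.1
    max_patches: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0 or self.lr_after <= 0:
            raise ParameterError("learning rates must be positive")
        if not 0 <= self.momentum < 1:
            raise ParameterError("momentum must lie in [0, 1)")
        if self.batch_size < 1:
            raise ParameterError("batch size must be >= 1")

    @classmethod
    def full(cls, **kw) -> "TrainConfig":
        return cls(**kw)

    @classmethod
    def reduced(cls, **kw) -> "TrainConfig":
        kw.setdefault("epochs", 5)
        kw.setdefault("max_patches", 10_000)
        return cls(**kw)

    def rate_at(self, epoch: int) -> float:
        """Learning rate for a 1-based epoch index."""
        return self.lr if epoch < self.lr_drop_epoch else self.lr_after


def decay_term(model: PatchClassifier, weight_decay: float) -> float:
    return weight_decay * 0.5 * sum(
        float((model.params[k] ** 2).sum()) for k in model.WEIGHT_KEYS
    )


def loss(model: PatchClassifier, patches, labels, weight_decay: float = 5e-4):
    """Objective value on one batch: mean cross-entropy + weight decay."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ParameterError("empty batch")
    x = model.prepare(patches)
    logits, _ = model.forward(x)
    ce, _, _ = L.softmax_ce(logits, labels)
    return float(ce) + decay_term(model, weight_decay)


def loss_and_grads(model: PatchClassifier, patches, labels,
                   weight_decay: float = 5e-4):
    """(objective, gradient dict) for one batch, decay included in both."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ParameterError("empty batch")
    x = model.prepare(patches)
    logits, caches = model.forward(x, need_cache=True)
    ce, _, dlogits = L.softmax_ce(logits, labels)
    grads = model.backward(dlogits, caches)
    for k in model.WEIGHT_KEYS:
        grads[k] = grads[k] + weight_decay * model.params[k]
    return float(ce) + decay_term(model, weight_decay), grads


def train(model: PatchClassifier, patches, labels,
          config: TrainConfig = None) -> PatchClassifier:
    """Train in place; returns the model with a filled per-epoch log.

    A seeded holdout split provides the per-epoch accuracy entry; all
    shuffling flows from ``config.seed``.
    """
    cfg = config or TrainConfig()
    x = np.asarray(patches)
    y = np.asarray(labels)
    if x.shape[0] != y.shape[0]:
        raise ParameterError("patch and label counts differ")
    rng = np.random.default_rng(cfg.seed)
    if cfg.max_patches is not None and x.shape[0] > cfg.max_patches:
        pick = rng.choice(x.shape[0], size=cfg.max_patches, replace=False)
        x, y = x[pick], y[pick]
    if x.shape[0] < cfg.batch_size:
        raise ParameterError(
            f"need at least one batch ({cfg.batch_size} patches), "
            f"got {x.shape[0]}"
        )
    n_hold = int(round(cfg.holdout_fraction * x.shape[0]))
    order = rng.permutation(x.shape[0])
    hold, tr = order[:n_hold], order[n_hold:]
    x_tr, y_tr = x[tr], y[tr]
    x_ho, y_ho = x[hold], y[hold]

    vel = {k: np.zeros_like(v) for k, v in model.params.items()}
    for epoch in range(1, cfg.epochs + 1):
        lr = cfg.rate_at(epoch)
        perm = rng.permutation(x_tr.shape[0])
        n_batches = x_tr.shape[0] // cfg.batch_size
        t0 = time.time()
        total = 0.0
        for b in range(n_batches):
            idx = perm[b * cfg.batch_size : (b + 1) * cfg.batch_size]
            obj, grads = loss_and_grads(model, x_tr[idx], y_tr[idx],
                                        cfg.weight_decay)
            total += obj
            for k, g in grads.items():
                vel[k] = cfg.momentum * vel[k] - lr * g.astype(model.dtype)
                model.params[k] += vel[k]
        acc = np.nan
        if x_ho.shape[0]:
            pred, _ = model.predict(x_ho)
            acc = float((pred == y_ho).mean())
        entry = {
            "epoch": epoch,
            "lr": lr,
            "mean_loss": total / max(n_batches, 1),
            "holdout_accuracy": acc,
            "seconds": round(time.time() - t0, 2),
        }
        model.log.append(entry)
        logger.info(
            "epoch %d/%d lr=%g loss=%.4f holdout=%.4f (%.1fs)",
            epoch, cfg.epochs, lr, entry["mean_loss"], acc, entry["seconds"],
        )
    model.fingerprint = dataclasses.asdict(cfg)
    return model
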