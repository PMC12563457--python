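"""Dataset splitting, data-reduction scenarios, and the optimization loops.

The base protocol splits a labeled set 70/20/10 into train/validation/test
by stratified shuffling.  A reduction scenario removes a fixed fraction
(20, 50 or 70 percent) from the train and validation partitions only; the
test partition never changes, so every scenario is scored on the same
held-out images.

Training is plain mini-batch Adam at the study's settings (batch 32,
learning rate 1e-4 by default, fixed epoch counts, no early stopping).
Pretext training holds out 20 percent of the pretext samples for
validation, grouped by source image so an original and its transformed
sibling never straddle the fold boundary.  Accuracy is the fraction of
thresholded predictions (cut-off 0.5) that match the labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .models import BuiltModel
from .pretext import (LossSpec, PretextDataset, bce_loss, mse_loss,
                      nt_xent_loss_and_grad)
from .synthetic import ImageSet

__all__ = [
    "SplitPlan",
    "TrainConfig",
    "TrainLog",
    "ALLOWED_REDUCTIONS",
    "split_sizes",
    "split_dataset",
    "train_pretext",
    "train_downstream",
    "accuracy",
]

ALLOWED_REDUCTIONS = (0.0, 0.2, 0.5, 0.7)


@dataclass(frozen=True)
class SplitPlan:
    """70/20/10 stratified split with an optional train+val reduction."""

    train_frac: float = 0.70
    val_frac: float = 0.20
    test_frac: float = 0.10
    reduction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if abs(self.train_frac + self.val_frac + self.test_frac - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if not any(abs(self.reduction - r) < 1e-12 for r in ALLOWED_REDUCTIONS):
            raise ValueError(
                f"reduction must be one of {ALLOWED_REDUCTIONS}, "
                f"got {self.reduction}")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (Adam, fixed epochs, BCE/MSE/NT-Xent loss)."""

    batch_size: int = 32
    epochs: int = 10
    learning_rate: float = 1e-4
    loss: LossSpec = field(default_factory=LossSpec)
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size must be >= 1 and epochs >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


class TrainLog:
    """Per-epoch train/val loss and accuracy plus a final weight checksum."""

    def __init__(self):
        self._rows: list[dict] = []
        self.final_checksum: str | None = None

    def append(self, **row) -> None:
        self._rows.append(row)

    def to_frame(self) -> pd.DataFrame:
        cols = ["epoch", "train_loss", "val_loss", "train_acc", "val_acc"]
        return pd.DataFrame(self._rows, columns=cols)

    def __len__(self) -> int:
        return len(self._rows)


def split_sizes(n_total: int, plan: SplitPlan) -> tuple[int, int, int]:
    """Floor-based partition sizes after reduction (test takes the remainder)."""
    n_train = int(np.floor(plan.train_frac * n_total))
    n_val = int(np.floor(plan.val_frac * n_total))
    n_test = n_total - n_train - n_val
    keep = 1.0 - plan.reduction
    return (int(np.floor(keep * n_train)), int(np.floor(keep * n_val)), n_test)


def _stratified_order(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permutation whose every prefix is class-balanced to within one image.

    Items are shuffled within class, assigned evenly spaced fractional
    positions, and merged by position, which interleaves classes
    proportionally to their sizes.
    """
    order, positions = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        order.append(idx)
        positions.append((np.arange(len(idx)) + rng.random()) / len(idx))
    order = np.concatenate(order)
    positions = np.concatenate(positions)
    return order[np.argsort(positions, kind="stable")]


def split_dataset(image_set: ImageSet,
                  plan: SplitPlan) -> tuple[ImageSet, ImageSet, ImageSet]:
    """Stratified train/val/test split; reduction trims train and val only."""
    n = len(image_set)
    if n < 10:
        raise ValueError(f"need at least 10 samples to split, got {n}")
    rng = np.random.default_rng(plan.seed)
    order = _stratified_order(image_set.labels, rng)
    full_train = int(np.floor(plan.train_frac * n))
    full_val = int(np.floor(plan.val_frac * n))
    n_train, n_val, _ = split_sizes(n, plan)
    train_idx = order[:full_train][:n_train]
    val_idx = order[full_train:full_train + full_val][:n_val]
    test_idx = order[full_train + full_val:]
    return (image_set.subset(train_idx), image_set.subset(val_idx),
            image_set.subset(test_idx))


def accuracy(y_true: np.ndarray, scores: np.ndarray,
             threshold: float = 0.5) -> float:
    """Fraction of predictions on the right side of the decision threshold."""
    pred = (np.asarray(scores) >= threshold).astype(np.int64)
    return float(np.mean(pred == np.asarray(y_true)))


def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield perm[i:i + batch_size]


def _train_binary(model: BuiltModel, x, y, xv, yv, cfg: TrainConfig,
                  log: TrainLog) -> None:
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.net.params(), lr=cfg.learning_rate)
    y = np.asarray(y, dtype=np.float64)
    for epoch in range(cfg.epochs):
        losses, accs = [], []
        for batch in _epoch_batches(len(x), cfg.batch_size, rng):
            xb = np.asarray(x[batch], dtype=np.float32)
            yb = y[batch]
            p = model.net.forward(xb, train=True, rng=rng)[:, 0]
            losses.append(bce_loss(yb, p, cfg.loss.probability_clip))
            accs.append(accuracy(yb, p))
            delta = ((p - yb) / len(xb)).astype(p.dtype)
            model.net.zero_grad()
            model.net.backward(delta[:, None], start=-2)
            opt.step()
        pv = model.predict(xv)
        log.append(epoch=epoch, train_loss=float(np.mean(losses)),
                   val_loss=bce_loss(yv, pv, cfg.loss.probability_clip),
                   train_acc=float(np.mean(accs)), val_acc=accuracy(yv, pv))


def _train_mse(model: BuiltModel, x, t, xv, tv, cfg: TrainConfig,
               log: TrainLog) -> None:
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.net.params(), lr=cfg.learning_rate)
    for epoch in range(cfg.epochs):
        losses = []
        for batch in _epoch_batches(len(x), cfg.batch_size, rng):
            xb = np.asarray(x[batch], dtype=np.float32)
            tb = np.asarray(t[batch], dtype=np.float32)
            out = model.net.forward(xb, train=True, rng=rng)
            losses.append(mse_loss(tb, out))
            dout = (2.0 * (out - tb) / out.size).astype(out.dtype)
            model.net.zero_grad()
            model.net.backward(dout)
            opt.step()
        vout = model.predict(xv)
        log.append(epoch=epoch, train_loss=float(np.mean(losses)),
                   val_loss=mse_loss(tv, vout),
                   train_acc=np.nan, val_acc=np.nan)


def _train_contrastive(model: BuiltModel, v1, v2, v1v, v2v, cfg: TrainConfig,
                       log: TrainLog) -> None:
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.net.params(), lr=cfg.learning_rate)
    tau = cfg.loss.temperature
    for epoch in range(cfg.epochs):
        losses = []
        for batch in _epoch_batches(len(v1), cfg.batch_size, rng):
            if len(batch) < 2:
                continue  # NT-Xent needs at least two pairs
            xb = np.empty((2 * len(batch), *v1.shape[1:]), dtype=np.float32)
            xb[0::2] = v1[batch]
            xb[1::2] = v2[batch]
            z = model.net.forward(xb, train=True, rng=rng)
            loss, dz = nt_xent_loss_and_grad(z, temperature=tau)
            losses.append(loss)
            model.net.zero_grad()
            model.net.backward(dz.astype(z.dtype))
            opt.step()
        val_loss = np.nan
        if len(v1v) >= 2:
            zv = np.empty((2 * len(v1v), z.shape[1]), dtype=np.float64)
            zv[0::2] = model.predict(v1v)
            zv[1::2] = model.predict(v2v)
            val_loss, _ = nt_xent_loss_and_grad(zv, temperature=tau)
        log.append(epoch=epoch, train_loss=float(np.mean(losses)),
                   val_loss=val_loss, train_acc=np.nan, val_acc=np.nan)


def _grouped_holdout(dataset: PretextDataset, frac: float,
                     rng: np.random.Generator):
    """80/20 index split keeping all samples of a source image together."""
    sources = dataset.provenance["source_id"].to_numpy()
    unique = pd.unique(sources)
    unique = unique[rng.permutation(len(unique))]
    n_train_src = int(np.floor((1.0 - frac) * len(unique)))
    train_src = set(unique[:n_train_src])
    mask = np.array([s in train_src for s in sources])
    return np.flatnonzero(mask), np.flatnonzero(~mask)


def train_pretext(dataset: PretextDataset, model: BuiltModel,
                  cfg: TrainConfig, val_frac: float = 0.2
                  ) -> tuple[BuiltModel, TrainLog]:
    """Train a pretext model in place; returns the model and its log."""
    expected = {"noise": "bce", "rotation": "bce",
                "reconstruction": "mse", "contrastive": "nt_xent"}
    if cfg.loss.kind != expected[dataset.task_kind]:
        raise ValueError(f"loss {cfg.loss.kind!r} incompatible with "
                         f"task {dataset.task_kind!r}")
    log = TrainLog()
    if cfg.epochs == 0:
        log.final_checksum = model.checksum()
        return model, log
    rng = np.random.default_rng(cfg.seed + 1)
    tr, va = _grouped_holdout(dataset, val_frac, rng)
    if dataset.task_kind in ("noise", "rotation"):
        _train_binary(model, dataset.inputs[tr], dataset.labels[tr],
                      dataset.inputs[va], dataset.labels[va], cfg, log)
    elif dataset.task_kind == "reconstruction":
        _train_mse(model, dataset.inputs[tr], dataset.targets[tr],
                   dataset.inputs[va], dataset.targets[va], cfg, log)
    else:
        _train_contrastive(model, dataset.inputs[tr], dataset.views2[tr],
                           dataset.inputs[va], dataset.views2[va], cfg, log)
    log.final_checksum = model.checksum()
    return model, log


def train_downstream(model: BuiltModel, train_set: ImageSet,
                     val_set: ImageSet, cfg: TrainConfig
                     ) -> tuple[BuiltModel, TrainLog]:
    """Fine-tune a post-surgery classifier on the class labels."""
    if model.kind != "binary":
        raise ValueError("downstream training needs a binary classifier")
    log = TrainLog()
    if cfg.epochs == 0:
        log.final_checksum = model.checksum()
        return model, log
    _train_binary(model, train_set.images, train_set.labels,
                  val_set.images, val_set.labels, cfg, log)
    log.final_checksum = model.checksum()
    return model, log
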