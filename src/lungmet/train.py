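"""Dataset splitting, cosine-annealed learning rate, and the training loop.

Training follows a single cosine-annealing cycle: the learning rate starts
at ``lr_max`` (0.001 by default), decays as
``lr(t) = lr_min + (lr_max - lr_min) * (1 + cos(pi * t / epochs)) / 2``
and reaches ``lr_min`` at the final epoch. Slices are split 80/20 into
training and validation at the slice level (a group-aware option avoids
same-animal leakage when stack identifiers are supplied). The loop uses
Adam and keeps the weights of the epoch with the best validation IoU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .layers import Adam
from .loss import LossConfig, combined_loss
from .network import UNet3Plus

__all__ = [
    "TrainConfig",
    "TrainingDiverged",
    "split_dataset",
    "cosine_lr",
    "train_model",
]


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    lr_max: float = 0.001
    lr_min: float = 0.0
    split_ratio: float = 0.8
    batch_size: int = 32
    seed: int = 0
    optimizer_name: str = "adam"

    def __post_init__(self):
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError(f"split_ratio must be in (0, 1), got {self.split_ratio}")
        if self.lr_min > self.lr_max or self.lr_min < 0:
            raise ValueError("need 0 <= lr_min <= lr_max")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.optimizer_name.lower() != "adam":
            raise ValueError(f"unknown optimizer {self.optimizer_name!r}")


def split_dataset(items: Sequence, split_ratio: float = 0.8, seed: int = 0,
                  groups: Sequence | None = None):
    """Shuffle and partition items into (train, val).

    Without ``groups`` the split is at the item (slice) level with
    ``len(train) = floor(split_ratio * N)`` exactly. With ``groups`` (one
    hashable id per item, e.g. the source stack) whole groups are assigned
    to the training side until the target size would be exceeded, which
    prevents slices of one animal from straddling the split; the realised
    ratio is then only approximate.
    """
    items = list(items)
    n = len(items)
    if n == 0:
        return [], []
    rng = np.random.default_rng(seed)
    n_train = int(math.floor(split_ratio * n))
    if groups is None:
        order = rng.permutation(n)
        train_idx, val_idx = order[:n_train], order[n_train:]
    else:
        groups = list(groups)
        if len(groups) != n:
            raise ValueError("groups must have one entry per item")
        uniq = sorted(set(groups), key=repr)
        order = rng.permutation(len(uniq))
        chosen: set = set()
        count = 0
        for gi in order:
            g = uniq[gi]
            size = groups.count(g)
            if count + size <= n_train:
                chosen.add(g)
                count += size
        train_idx = [i for i in range(n) if groups[i] in chosen]
        val_idx = [i for i in range(n) if groups[i] not in chosen]
    return [items[i] for i in train_idx], [items[i] for i in val_idx]


def cosine_lr(epoch: int, config: TrainConfig) -> float:
    """Learning rate of one cosine annealing cycle at integer epoch t."""
    if not 0 <= epoch <= config.epochs:
        raise ValueError(f"epoch must be in [0, {config.epochs}], got {epoch}")
    span = config.lr_max - config.lr_min
    return config.lr_min + 0.5 * span * (1.0 + math.cos(math.pi * epoch / config.epochs))


def _per_class_iou(pred: np.ndarray, target: np.ndarray, num_classes: int):
    out = []
    for c in range(num_classes):
        p, g = pred == c, target == c
        union = (p | g).sum()
        out.append(float((p & g).sum() / union) if union else float("nan"))
    return out


def _validate(model, val_set, loss_config, batch_size):
    model.eval()
    losses, preds, targets = [], [], []
    with ad.no_grad():
        for lo in range(0, len(val_set), batch_size):
            chunk = val_set[lo : lo + batch_size]
            x = np.stack([im for im, _ in chunk])[:, None].astype(np.float32)
            y = np.stack([m for _, m in chunk])
            probs = model(Tensor(x))
            losses.append(combined_loss(probs, y, loss_config).item())
            preds.append(probs.data.argmax(axis=1))
            targets.append(y)
    ious = _per_class_iou(
        np.concatenate(preds), np.concatenate(targets), model.spec.num_classes
    )
    return float(np.mean(losses)), ious


def train_model(
    model: UNet3Plus,
    train_set: Sequence,
    val_set: Sequence,
    loss_config: LossConfig = LossConfig(),
    train_config: TrainConfig = TrainConfig(),
    verbose: bool = False,
):
    """Train the network; returns (best_state_dict, per-epoch metric log).

    ``train_set`` / ``val_set`` are sequences of ``(image, mask)`` 2D pairs
    with image intensities in [0, 1] and mask labels in {0, 1, 2}. The log
    has one row per epoch with the learning rate, mean training loss,
    validation loss and per-class validation IoU; the returned weights are
    those of the epoch with the highest mean foreground validation IoU
    (falling back to the final weights when no validation set is given).
    """
    if not train_set:
        raise ValueError("training set must be non-empty")
    cfg = train_config
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters())
    log: list[dict] = []
    best_score, best_state = -np.inf, None
    for epoch in range(cfg.epochs):
        lr = cosine_lr(epoch, cfg)
        model.train()
        order = rng.permutation(len(train_set))
        epoch_losses = []
        for lo in range(0, len(order), cfg.batch_size):
            chunk = [train_set[i] for i in order[lo : lo + cfg.batch_size]]
            x = np.stack([im for im, _ in chunk])[:, None].astype(np.float32)
            y = np.stack([m for _, m in chunk])
            probs = model(Tensor(x))
            loss = combined_loss(probs, y, loss_config)
            if not np.isfinite(loss.item()):
                raise TrainingDiverged(
                    f"non-finite loss {loss.item()} at epoch {epoch}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step(lr)
            epoch_losses.append(loss.item())
        row = {
            "epoch": epoch,
            "lr": lr,
            "train_loss": float(np.mean(epoch_losses)),
            "val_loss": float("nan"),
        }
        for c in range(model.spec.num_classes):
            row[f"val_iou_class{c}"] = float("nan")
        if val_set:
            val_loss, ious = _validate(model, val_set, loss_config, cfg.batch_size)
            row["val_loss"] = val_loss
            for c, v in enumerate(ious):
                row[f"val_iou_class{c}"] = v
            fg = [v for v in ious[1:] if not math.isnan(v)]
            score = float(np.mean(fg)) if fg else -np.inf
            if score > best_score:
                best_score, best_state = score, model.state_dict()
        log.append(row)
        if verbose:
            print(
                f"epoch {epoch:3d} lr {lr:.2e} train {row['train_loss']:.4f} "
                f"val {row['val_loss']:.4f}"
            )
    if best_state is None:
        best_state = model.state_dict()
    model.load_state_dict(best_state)
    return best_state, log
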