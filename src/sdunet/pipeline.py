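"""Training, evaluation and prediction orchestration.

Optimization follows the source setup at desk scale: Adam (beta1 0.9,
beta2 0.999, eps 1e-8) with learning rate 1e-4 for EM-style binary tasks
and 1e-5 for BRATs-style multi-class tasks by default, binary
cross-entropy or the combined BCE - soft-Dice objective, small batches
(default 2 — the micro-batch regime group normalization is built for).
Everything is driven by seeds: data shuffling and dropout derive their
generators from ``TrainConfig.seed``, so a (seed, config, data) triple
fixes the run bit-for-bit on one device.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.measure import label as _cc_label

from .metrics import (DEFAULT_THRESHOLDS, accuracy, confusion_counts, dice,
                      iou, maximal_score_over_thresholds)
from .nn import Model
from .objectives import LossConfig, combined_loss_t
from .synthetic_data import SyntheticSample, one_hot

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "Adam",
    "stack_samples",
    "train",
    "evaluate",
    "predict",
]

LOSSES = ("bce", "dice_bce")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings for one training run."""

    learning_rate: float = 1e-4
    epochs: int = 1
    steps_per_epoch: int = 100
    batch_size: int = 2
    loss: str = "bce"
    seed: int = 0
    checkpoint_dir: str | None = None

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.epochs < 1 or self.steps_per_epoch < 1:
            raise ValueError("epochs, steps_per_epoch, batch_size must be >= 1")
        if self.loss not in LOSSES:
            raise ValueError(f"loss must be one of {LOSSES}")


@dataclass
class TrainHistory:
    """Per-epoch loss/metric records for train and validation splits."""

    records: list[dict] = field(default_factory=list)

    def append(self, record: dict) -> None:
        for v in record.values():
            if isinstance(v, float) and not np.isfinite(v):
                raise ValueError(f"non-finite history value in {record}")
        self.records.append(record)

    def __len__(self):
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.records, **kwargs)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json(indent=2))

    def plot(self, path) -> None:
        """Render loss / Dice curves to an image file."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        epochs = [r["epoch"] for r in self.records]
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
        ax1.plot(epochs, [r["loss"] for r in self.records], label="train")
        if "val_loss" in self.records[0]:
            ax1.plot(epochs, [r["val_loss"] for r in self.records], label="val")
        ax1.set_xlabel("epoch"); ax1.set_ylabel("loss"); ax1.legend()
        ax2.plot(epochs, [r["dice"] for r in self.records], label="train")
        if "val_dice" in self.records[0]:
            ax2.plot(epochs, [r["val_dice"] for r in self.records], label="val")
        ax2.set_xlabel("epoch"); ax2.set_ylabel("Dice"); ax2.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


class Adam:
    """Adam optimizer over a model's parameter tensors."""

    def __init__(self, params: dict, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def stack_samples(samples: list[SyntheticSample],
                  num_classes: int | None = None):
    """Samples -> (images (n,H,W,C), targets (n,H,W,1) or (n,H,W,K))."""
    images = np.stack([s.image for s in samples])
    if images.ndim == 3:
        images = images[..., None]
    masks = np.stack([s.mask for s in samples])
    k = int(masks.max()) + 1 if num_classes is None else num_classes
    if k <= 2:
        targets = (masks > 0).astype(np.float64)[..., None]
    else:
        targets = np.stack([one_hot(m, k) for m in masks])
    return images, targets


def _loss_config(name: str) -> LossConfig:
    if name == "bce":
        return LossConfig(bce_weight=1.0, dice_weight=0.0)
    return LossConfig(bce_weight=1.0, dice_weight=1.0)


def _split_metrics(model: Model, x, y) -> dict:
    probs = _forward_in_batches(model, x)
    c = confusion_counts(probs, y, 0.5)
    from .objectives import bce_loss
    return {
        "loss": float(bce_loss(probs, y)),
        "accuracy": accuracy(c),
        "iou": iou(c),
        "dice": dice(c),
    }


def _forward_in_batches(model: Model, x, batch: int = 4) -> np.ndarray:
    outs = [model.forward(x[i:i + batch], training=False).value
            for i in range(0, len(x), batch)]
    return np.concatenate(outs, axis=0)


def train(model: Model, data, cfg: TrainConfig,
          val_data=None) -> TrainHistory:
    """Seeded end-to-end optimization of ``model`` on ``data``.

    ``data`` (and optional ``val_data``) is an (images, targets) pair as
    produced by :func:`stack_samples`.  Returns the per-epoch history;
    when ``cfg.checkpoint_dir`` is set, the best-validation-Dice weights
    (training Dice without a validation split) are saved there along with
    the history JSON.
    """
    x, y = data
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape[:3] != y.shape[:3]:
        raise ValueError(f"image/target shape mismatch: {x.shape} vs {y.shape}")
    n = len(x)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params, lr=cfg.learning_rate)
    loss_cfg = _loss_config(cfg.loss)
    history = TrainHistory()
    best_dice = -1.0
    ckpt_dir = Path(cfg.checkpoint_dir) if cfg.checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)

    order = rng.permutation(n)
    cursor = 0
    for epoch in range(1, cfg.epochs + 1):
        epoch_losses = []
        for _ in range(cfg.steps_per_epoch):
            if cursor + cfg.batch_size > n:
                order = rng.permutation(n)
                cursor = 0
            idx = order[cursor:cursor + cfg.batch_size]
            cursor += cfg.batch_size
            pred = model.forward(x[idx], training=True, rng=rng)
            loss = combined_loss_t(pred, y[idx], loss_cfg)
            if not np.isfinite(loss.value):
                raise RuntimeError(
                    f"non-finite loss {loss.value!r} at epoch {epoch}; "
                    "check learning rate and input scaling")
            model.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.value))

        record = {"epoch": epoch, **_split_metrics(model, x, y)}
        record["step_loss_mean"] = float(np.mean(epoch_losses))
        if val_data is not None:
            vm = _split_metrics(model, np.asarray(val_data[0], dtype=np.float64),
                                np.asarray(val_data[1], dtype=np.float64))
            record.update({f"val_{k}": v for k, v in vm.items()})
        history.append(record)

        monitor = record.get("val_dice", record["dice"])
        if ckpt_dir and monitor > best_dice:
            best_dice = monitor
            model.save_weights(ckpt_dir / "best_weights.npz")
    if ckpt_dir:
        history.save(ckpt_dir / "history.json")
    return history


def evaluate(model: Model, data, thresholds=DEFAULT_THRESHOLDS) -> dict:
    """Pixel metrics (accuracy / mean IOU / Dice at threshold 0.5) and, for
    binary in-out outputs, mean maximal V^Rand / V^Info over ``thresholds``.

    The boundary-probability map fed to the Rand/information scores is
    ``1 - p(interior)``; ground-truth segments are the 4-connected
    components of the in-out mask's foreground.
    """
    x, y = data
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) == 0:
        raise ValueError("empty dataset")
    probs = _forward_in_batches(model, x)
    c = confusion_counts(probs, y, 0.5)
    report = {
        "accuracy": accuracy(c),
        "mean_iou": iou(c),
        "dice": dice(c),
        "n_images": int(len(x)),
    }
    if probs.shape[-1] == 1:
        rands, infos = [], []
        for i in range(len(x)):
            truth_seg = _cc_label(y[i, ..., 0] > 0.5, connectivity=1,
                                  background=0)
            if truth_seg.max() == 0:
                continue  # no foreground segments to score against
            vr, vi = maximal_score_over_thresholds(
                1.0 - probs[i, ..., 0], truth_seg, thresholds)
            rands.append(vr)
            infos.append(vi)
        if rands:
            report["v_rand"] = float(np.mean(rands))
            report["v_info"] = float(np.mean(infos))
    return report


def predict(model: Model, images, batch: int = 4) -> np.ndarray:
    """Probability maps for an image stack; deterministic given weights.

    Spatial sides must be divisible by 16; other sizes are reflect-padded
    (with a warning) and the output cropped back.
    """
    x = np.asarray(images, dtype=np.float64)
    if x.ndim == 3:
        x = x[None]
    n, h, w, c = x.shape
    div = 16
    ph = (-h) % div
    pw = (-w) % div
    if ph or pw:
        warnings.warn(
            f"input {h}x{w} not divisible by {div}; reflect-padding to "
            f"{h + ph}x{w + pw}", stacklevel=2)
        x = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)), mode="reflect")
    out = _forward_in_batches(model, x, batch=batch)
    return out[:, :h, :w, :]
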