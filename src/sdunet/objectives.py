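"""Training losses: binary cross-entropy, soft Dice, and their weighted sum.

Each loss exists in two forms that share one formula: a plain-numpy
function (the reference contract, used for reporting) and a differentiable
builder over :mod:`sdunet.autodiff` tensors (used in training).  The
combined loss is ``bce_weight * BCE - dice_weight * softDice`` — the Dice
term enters negatively since the coefficient is maximized.

Multi-channel inputs (one-hot multi-class masks) are handled by the same
expressions: BCE averages over all pixels and channels, and soft Dice is
computed per channel and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad

__all__ = [
    "LossConfig",
    "bce_loss",
    "soft_dice",
    "combined_loss",
    "bce_loss_t",
    "soft_dice_t",
    "combined_loss_t",
    "CLIP",
]

CLIP = 1e-7  # probability clipping, avoids log(0)


@dataclass(frozen=True)
class LossConfig:
    """Weights of the combined objective and the soft-Dice stabilizer."""

    bce_weight: float = 1.0
    dice_weight: float = 1.0
    smooth: float = 1.0

    def __post_init__(self):
        if self.bce_weight < 0 or self.dice_weight < 0:
            raise ValueError("loss weights must be non-negative")
        if self.bce_weight + self.dice_weight <= 0:
            raise ValueError("at least one loss weight must be positive")
        if self.smooth <= 0:
            raise ValueError("smooth must be positive")


def _check_shapes(pred, truth):
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")


# ----------------------------------------------------------------------
# numpy reference forms
# ----------------------------------------------------------------------

def bce_loss(pred_prob, truth) -> float:
    """Mean over pixels of -[y log p + (1 - y) log(1 - p)], p clipped."""
    p = np.clip(np.asarray(pred_prob, dtype=np.float64), CLIP, 1 - CLIP)
    y = np.asarray(truth, dtype=np.float64)
    _check_shapes(p, y)
    return float(np.mean(-(y * np.log(p) + (1 - y) * np.log1p(-p))))


def soft_dice(pred_prob, truth, smooth: float = 1.0) -> float:
    """Differentiable Dice: (2 sum(p y) + s) / (sum p + sum y + s),
    per channel then averaged when a channel axis is present."""
    p = np.asarray(pred_prob, dtype=np.float64)
    y = np.asarray(truth, dtype=np.float64)
    _check_shapes(p, y)
    if p.ndim == 4 and p.shape[-1] > 1:
        axes = tuple(range(p.ndim - 1))
    else:
        axes = None
    inter = (p * y).sum(axis=axes)
    sums = p.sum(axis=axes) + y.sum(axis=axes)
    return float(np.mean((2 * inter + smooth) / (sums + smooth)))


def combined_loss(pred_prob, truth, cfg: LossConfig = LossConfig()) -> float:
    """bce_weight * BCE - dice_weight * softDice."""
    out = 0.0
    if cfg.bce_weight:
        out += cfg.bce_weight * bce_loss(pred_prob, truth)
    if cfg.dice_weight:
        out -= cfg.dice_weight * soft_dice(pred_prob, truth, cfg.smooth)
    return out


# ----------------------------------------------------------------------
# differentiable forms (autodiff tensors)
# ----------------------------------------------------------------------

def bce_loss_t(pred: ad.Tensor, truth) -> ad.Tensor:
    y = np.asarray(truth, dtype=np.float64)
    _check_shapes(pred.value, y)
    p = ad.clip(pred, CLIP, 1 - CLIP)
    ll = y * ad.log(p) + (1 - y) * ad.log(1 - p)
    return -ad.mean_(ll)


def soft_dice_t(pred: ad.Tensor, truth, smooth: float = 1.0) -> ad.Tensor:
    y = np.asarray(truth, dtype=np.float64)
    _check_shapes(pred.value, y)
    if pred.ndim == 4 and pred.shape[-1] > 1:
        axes = tuple(range(pred.ndim - 1))
        inter = ad.sum_(pred * y, axis=axes)
        sums = ad.sum_(pred, axis=axes) + y.sum(axis=axes)
        return ad.mean_((2 * inter + smooth) / (sums + smooth))
    inter = ad.sum_(pred * y)
    sums = ad.sum_(pred) + y.sum()
    return (2 * inter + smooth) / (sums + smooth)


def combined_loss_t(pred: ad.Tensor, truth,
                    cfg: LossConfig = LossConfig()) -> ad.Tensor:
    terms = []
    if cfg.bce_weight:
        terms.append(cfg.bce_weight * bce_loss_t(pred, truth))
    if cfg.dice_weight:
        terms.append(-cfg.dice_weight * soft_dice_t(pred, truth, cfg.smooth))
    out = terms[0]
    for t in terms[1:]:
        out = out + t
    return out
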