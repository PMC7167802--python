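"""Segmentation evaluation metrics.

Pixel-classification scores (accuracy, IOU/Jaccard, Dice) are computed
from a :class:`ConfusionCounts` tally of thresholded predictions.  The
segment-level scores are the foreground-restricted Rand F-score (V^Rand)
and information-theoretic F-score (V^Info) used for neuron-boundary
segmentation: both compare a predicted label image S against a ground
truth T over the pixels where T is foreground (T > 0), via the label
contingency table — never by explicit pair enumeration, which the test
suite uses only as an O(n^2) oracle.

Conventions
-----------
* Empty-union: IOU and Dice are 1.0 when prediction and truth are both
  empty (TP = FP = FN = 0) and 0.0 when exactly one side is empty.
* V^Rand: with n_ij the contingency counts over T-foreground pixels,
  pair counts SB = sum C(n_ij, 2), SS = sum C(s_i, 2), ST = sum C(t_j, 2);
  merge score SB/ST, split score SB/SS, and the equal-weight harmonic
  mean collapses to 2 SB / (SS + ST).
* V^Info: 2 I(S;T) / (H(S) + H(T)) from the same table, with 0 log 0 = 0;
  when both labelings are a single segment the score is 1 (identical
  partitions), and 0 when exactly one is.
* Pixels where the prediction is boundary (label 0) inside T's foreground
  form their own segment with id 0.
* Connected components of a thresholded boundary map are labeled with
  4-connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as _cc_label

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "accuracy",
    "iou",
    "dice",
    "foreground_restricted_rand_score",
    "information_theoretic_score",
    "boundary_map_to_segments",
    "maximal_score_over_thresholds",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN tallies of a binarized prediction."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.TN + other.TN,
                               self.FP + other.FP, self.FN + other.FN)


def confusion_counts(pred_prob, truth, threshold: float = 0.5) -> ConfusionCounts:
    """Binarize ``pred_prob`` at ``threshold`` and tally against ``truth``."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    p = np.asarray(pred_prob)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    pb = p >= threshold
    tb = t > 0.5
    tp = int(np.count_nonzero(pb & tb))
    tn = int(np.count_nonzero(~pb & ~tb))
    fp = int(np.count_nonzero(pb & ~tb))
    fn = int(np.count_nonzero(~pb & tb))
    return ConfusionCounts(tp, tn, fp, fn)


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / total."""
    if c.total == 0:
        raise ValueError("no evaluated pixels")
    return (c.TP + c.TN) / c.total


def iou(c: ConfusionCounts) -> float:
    """Jaccard index TP / (TP + FP + FN); 1.0 when both sides are empty."""
    denom = c.TP + c.FP + c.FN
    if denom == 0:
        return 1.0
    return c.TP / denom


def dice(c: ConfusionCounts) -> float:
    """Dice coefficient 2TP / (2TP + FP + FN); 1.0 when both sides are empty."""
    denom = 2 * c.TP + c.FP + c.FN
    if denom == 0:
        return 1.0
    return 2 * c.TP / denom


# ----------------------------------------------------------------------
# segment-level scores
# ----------------------------------------------------------------------

def _contingency(S, T) -> np.ndarray:
    """Joint label counts over T's foreground pixels (rows: S, cols: T)."""
    S = np.asarray(S)
    T = np.asarray(T)
    if S.shape != T.shape:
        raise ValueError(f"shape mismatch: {S.shape} vs {T.shape}")
    fg = T > 0
    if not fg.any():
        raise ValueError("ground truth has no foreground pixels")
    s = S[fg].ravel()
    t = T[fg].ravel()
    _, si = np.unique(s, return_inverse=True)
    _, ti = np.unique(t, return_inverse=True)
    table = np.zeros((si.max() + 1, ti.max() + 1), dtype=np.int64)
    np.add.at(table, (si, ti), 1)
    return table


def _pairs(counts: np.ndarray) -> int:
    c = counts.astype(np.int64)
    return int((c * (c - 1) // 2).sum())


def foreground_restricted_rand_score(S, T) -> float:
    """Rand F-score of S against T restricted to T's foreground.

    Equal-weight harmonic mean of the merge score P(same in T | same in S)
    and the split score P(same in S | same in T); 1.0 for identical
    partitions.
    """
    table = _contingency(S, T)
    sb = _pairs(table.ravel())
    ss = _pairs(table.sum(axis=1))
    st = _pairs(table.sum(axis=0))
    if ss + st == 0:      # every restricted pixel is its own segment in both
        return 1.0
    return 2.0 * sb / (ss + st)


def information_theoretic_score(S, T) -> float:
    """Mutual-information F-score 2 I(S;T) / (H(S) + H(T)) on T's foreground."""
    table = _contingency(S, T)
    n = table.sum()
    p = table / n
    ps = p.sum(axis=1)
    pt = p.sum(axis=0)
    hs = -np.sum(ps[ps > 0] * np.log(ps[ps > 0]))
    ht = -np.sum(pt[pt > 0] * np.log(pt[pt > 0]))
    if hs == 0.0 and ht == 0.0:
        return 1.0    # both single-segment: identical partitions
    nz = p > 0
    mi = float(np.sum(p[nz] * (np.log(p[nz])
                               - np.log(np.outer(ps, pt)[nz]))))
    mi = max(mi, 0.0)  # clip tiny negative rounding residue
    return 2.0 * mi / (hs + ht)


def boundary_map_to_segments(boundary_prob, threshold: float) -> np.ndarray:
    """Binarize a boundary-probability image at ``threshold`` (boundary
    where prob >= threshold) and label connected components of the
    non-boundary pixels with 4-connectivity; boundary pixels get id 0."""
    b = np.asarray(boundary_prob)
    if b.ndim != 2:
        raise ValueError("boundary map must be 2-D")
    interior = b < threshold
    return _cc_label(interior, connectivity=1, background=0).astype(np.int64)


def maximal_score_over_thresholds(boundary_prob, T,
                                  thresholds=DEFAULT_THRESHOLDS):
    """Best (V^Rand, V^Info) of a boundary-probability map over a
    threshold sweep.

    For each threshold the map is binarized, non-boundary pixels are
    labeled into segments, and both scores are computed against the
    ground-truth label image ``T``; the maxima over the sweep are
    returned.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("threshold sweep must be non-empty")
    if any(not 0.0 < t < 1.0 for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1)")
    best_rand = 0.0
    best_info = 0.0
    for thr in thresholds:
        seg = boundary_map_to_segments(boundary_prob, thr)
        best_rand = max(best_rand, foreground_restricted_rand_score(seg, T))
        best_info = max(best_info, information_theoretic_score(seg, T))
    return best_rand, best_info
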