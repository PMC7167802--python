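"""Metric oracles: hand arithmetic for the confusion-based scores, and
O(n^2) pair-enumeration / direct-entropy oracles for V^Rand and V^Info."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sdunet.metrics import (ConfusionCounts, accuracy, boundary_map_to_segments,
                            confusion_counts, dice,
                            foreground_restricted_rand_score,
                            information_theoretic_score, iou,
                            maximal_score_over_thresholds)


# ----------------------------------------------------------------------
# confusion-based scores
# ----------------------------------------------------------------------

class TestConfusion:
    def test_exact_prediction_has_no_errors(self, rng):
        t = (rng.random((8, 8)) > 0.5).astype(float)
        c = confusion_counts(t, t, 0.5)
        assert c.FP == c.FN == 0
        assert c.TP + c.TN == 64

    def test_all_ones_prediction(self, rng):
        t = (rng.random((10, 10)) > 0.7).astype(float)
        k = int(t.sum())
        c = confusion_counts(np.ones_like(t), t, 0.5)
        assert (c.TP, c.FP, c.TN, c.FN) == (k, 100 - k, 0, 0)

    def test_matches_per_pixel_tally(self, rng):
        p = rng.random((16, 16))
        t = (rng.random((16, 16)) > 0.5).astype(float)
        c = confusion_counts(p, t, 0.4)
        tp = tn = fp = fn = 0
        for i in range(16):
            for j in range(16):
                pred = p[i, j] >= 0.4
                truth = t[i, j] > 0.5
                tp += pred and truth
                tn += (not pred) and (not truth)
                fp += pred and not truth
                fn += (not pred) and truth
        assert (c.TP, c.TN, c.FP, c.FN) == (tp, tn, fp, fn)

    def test_hand_arithmetic_scores(self):
        c = ConfusionCounts(TP=8, TN=2, FP=1, FN=1)
        assert accuracy(c) == pytest.approx(0.8333, abs=5e-5)
        assert iou(c) == pytest.approx(0.8000, abs=5e-5)
        assert dice(c) == pytest.approx(0.8889, abs=5e-5)

    def test_perfect_prediction_scores_one(self):
        c = ConfusionCounts(TP=5, TN=5, FP=0, FN=0)
        assert accuracy(c) == iou(c) == dice(c) == 1.0

    def test_empty_union_conventions(self):
        both_empty = ConfusionCounts(TP=0, TN=10, FP=0, FN=0)
        assert iou(both_empty) == dice(both_empty) == 1.0
        one_empty = ConfusionCounts(TP=0, TN=9, FP=1, FN=0)
        assert iou(one_empty) == dice(one_empty) == 0.0

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            confusion_counts(np.zeros((2, 2)), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            confusion_counts(np.zeros((2, 2)), np.zeros((2, 2)), threshold=1.5)


@settings(derandomize=True, max_examples=1000, deadline=None)
@given(tp=st.integers(0, 500), fp=st.integers(0, 500), fn=st.integers(0, 500))
def test_dice_iou_identity(tp, fp, fn):
    """Dice = 2*IOU/(1+IOU) on arbitrary confusion tables."""
    c = ConfusionCounts(TP=tp, TN=3, FP=fp, FN=fn)
    j = iou(c)
    assert dice(c) == pytest.approx(2 * j / (1 + j), abs=1e-12)


# ----------------------------------------------------------------------
# V^Rand / V^Info with pair-enumeration oracles
# ----------------------------------------------------------------------

def _rand_oracle(S, T):
    """Explicit enumeration over all unordered pixel pairs of T's foreground."""
    fg = np.argwhere(T > 0)
    sb = ss = st_ = 0
    for (a, b) in itertools.combinations(range(len(fg)), 2):
        pa, pb = tuple(fg[a]), tuple(fg[b])
        same_s = S[pa] == S[pb]
        same_t = T[pa] == T[pb]
        sb += same_s and same_t
        ss += same_s
        st_ += same_t
    if ss + st_ == 0:
        return 1.0
    return 2.0 * sb / (ss + st_)


def _info_oracle(S, T):
    """Direct H/I computation from empirical joint frequencies."""
    fg = T > 0
    s, t = S[fg].ravel(), T[fg].ravel()
    n = len(s)
    joint = {}
    for a, b in zip(s, t):
        joint[(a, b)] = joint.get((a, b), 0) + 1
    ps, pt = {}, {}
    for (a, b), c in joint.items():
        ps[a] = ps.get(a, 0) + c
        pt[b] = pt.get(b, 0) + c
    hs = -sum(c / n * np.log(c / n) for c in ps.values())
    ht = -sum(c / n * np.log(c / n) for c in pt.values())
    if hs == 0 and ht == 0:
        return 1.0
    mi = sum(c / n * np.log((c / n) / (ps[a] / n * pt[b] / n))
             for (a, b), c in joint.items())
    return 2.0 * mi / (hs + ht)


class TestSegmentScores:
    def test_identical_segmentation_scores_one(self, rng):
        t = rng.integers(0, 4, size=(10, 10))
        assert foreground_restricted_rand_score(t, t) == pytest.approx(1.0)
        assert information_theoretic_score(t, t) == pytest.approx(1.0)

    def test_merged_segments_hand_case(self):
        # T: two 2-pixel segments; S: one 4-pixel segment ->
        # same-in-both = 2, same-in-S = 6, same-in-T = 2 -> 0.5
        t = np.array([[1, 1, 2, 2]])
        s = np.array([[1, 1, 1, 1]])
        assert foreground_restricted_rand_score(s, t) == pytest.approx(0.5)
        assert _rand_oracle(s, t) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rand_matches_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.integers(0, 5, size=(12, 12))
        t = rng.integers(0, 5, size=(12, 12))
        got = foreground_restricted_rand_score(s, t)
        assert got == pytest.approx(_rand_oracle(s, t), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_info_matches_direct_entropy(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.integers(0, 5, size=(12, 12))
        t = rng.integers(0, 5, size=(12, 12))
        got = information_theoretic_score(s, t)
        assert got == pytest.approx(_info_oracle(s, t), abs=1e-12)

    def test_independent_labelings_score_near_zero(self):
        rng = np.random.default_rng(3)
        s = rng.integers(1, 10, size=(64, 64))
        t = rng.integers(1, 10, size=(64, 64))
        assert information_theoretic_score(s, t) < 0.05

    def test_scores_invariant_to_relabeling(self, rng):
        s = rng.integers(0, 6, size=(10, 10))
        t = rng.integers(0, 6, size=(10, 10))
        perm = rng.permutation(100) + 10
        s2 = np.where(s > 0, perm[s], 0)
        assert foreground_restricted_rand_score(s, t) == pytest.approx(
            foreground_restricted_rand_score(s2, t), abs=1e-12)
        assert information_theoretic_score(s, t) == pytest.approx(
            information_theoretic_score(s2, t), abs=1e-12)

    def test_scores_lie_in_unit_interval(self, rng):
        for _ in range(10):
            s = rng.integers(0, 8, size=(9, 9))
            t = rng.integers(0, 8, size=(9, 9))
            if not (t > 0).any():
                continue
            for fn in (foreground_restricted_rand_score,
                       information_theoretic_score):
                assert 0.0 <= fn(s, t) <= 1.0

    def test_empty_foreground_rejected(self):
        with pytest.raises(ValueError):
            foreground_restricted_rand_score(np.ones((3, 3)), np.zeros((3, 3)))


class TestMaximalScores:
    def _truth(self):
        # two interiors separated by a boundary column
        t = np.zeros((8, 8), dtype=int)
        t[:, :3] = 1
        t[:, 4:] = 2
        return t

    def test_perfect_boundary_map_scores_one(self):
        t = self._truth()
        bmap = (t == 0).astype(float) * 0.9 + 0.05
        vr, vi = maximal_score_over_thresholds(bmap, t, [0.5])
        assert vr == pytest.approx(1.0)
        assert vi == pytest.approx(1.0)

    def test_constant_half_map_two_case_evaluation(self):
        t = self._truth()
        bmap = np.full((8, 8), 0.5)
        vr, vi = maximal_score_over_thresholds(bmap, t, [0.3, 0.7])
        cases = [boundary_map_to_segments(bmap, 0.3),
                 boundary_map_to_segments(bmap, 0.7)]
        assert vr == pytest.approx(max(_rand_oracle(c, t) for c in cases))
        assert vi == pytest.approx(max(_info_oracle(c, t) for c in cases))

    def test_maxima_monotone_in_threshold_set(self, rng):
        t = self._truth()
        bmap = rng.random((8, 8))
        few = maximal_score_over_thresholds(bmap, t, [0.4, 0.6])
        more = maximal_score_over_thresholds(bmap, t, [0.2, 0.4, 0.6, 0.8])
        assert more[0] >= few[0]
        assert more[1] >= few[1]

    def test_connectivity_is_4_not_8(self):
        # diagonal contact must NOT merge components
        bmap = np.array([[0.0, 1.0], [1.0, 0.0]])
        seg = boundary_map_to_segments(bmap, 0.5)
        assert seg[0, 0] != 0 and seg[1, 1] != 0
        assert seg[0, 0] != seg[1, 1]

    def test_empty_threshold_list_rejected(self):
        with pytest.raises(ValueError):
            maximal_score_over_thresholds(np.zeros((4, 4)), np.ones((4, 4)), [])
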