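"""Hand-arithmetic oracles and invariants of the three primitives:
weight standardization, group normalization, depthwise separable conv."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sdunet.layers import (FeatureMap, GroupNormParams, WeightTensor,
                           depthwise_separable_conv, group_normalize,
                           resolve_num_groups, weight_standardize)


# ----------------------------------------------------------------------
# weight standardization
# ----------------------------------------------------------------------

class TestWeightStandardize:
    def test_constant_depthwise_filter_maps_to_zero(self):
        w = np.full((3, 3, 2, 1), 0.7)
        out = weight_standardize(w, depthwise=True)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)
        assert np.all(np.isfinite(out))

    def test_hand_arithmetic_three_weights(self):
        # one output channel, weights [1,2,3]: mu=2, sigma=sqrt(2/3)
        w = np.array([1.0, 2.0, 3.0]).reshape(1, 1, 3, 1)
        out = weight_standardize(w, eps=1e-12).ravel()
        np.testing.assert_allclose(out, [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_output_is_standardized_per_channel(self, rng):
        w = rng.standard_normal((3, 3, 5, 7))
        out = weight_standardize(w, eps=1e-9)
        means = out.mean(axis=(0, 1, 2))
        stds = out.std(axis=(0, 1, 2))
        np.testing.assert_allclose(means, 0.0, atol=1e-12)
        np.testing.assert_allclose(stds, 1.0, atol=1e-6)

    def test_depthwise_groups_are_per_channel(self, rng):
        w = rng.standard_normal((3, 3, 4, 1))
        out = weight_standardize(w, eps=1e-9, depthwise=True)
        np.testing.assert_allclose(out.mean(axis=(0, 1)), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=(0, 1)), 1.0, atol=1e-6)

    def test_idempotent_in_small_eps_limit(self, rng):
        w = rng.standard_normal((3, 3, 4, 6))
        eps = 1e-10
        once = weight_standardize(w, eps=eps)
        twice = weight_standardize(once, eps=eps)
        assert np.abs(twice - once).max() < 1e-6

    def test_shape_preserved_and_wrapper_roundtrip(self, rng):
        wt = WeightTensor(rng.standard_normal((3, 3, 2, 1)), depthwise=True)
        out = weight_standardize(wt)
        assert isinstance(out, WeightTensor)
        assert out.values.shape == wt.values.shape

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            weight_standardize(np.zeros((3, 3, 2)))
        with pytest.raises(ValueError):
            weight_standardize(np.zeros((3, 3, 2, 2)), eps=0.0)


# ----------------------------------------------------------------------
# group normalization
# ----------------------------------------------------------------------

def _gn_oracle(x, groups, eps):
    """Direct two-pass mean/variance normalization, one example + group
    at a time."""
    n, h, w, c = x.shape
    cg = c // groups
    out = np.empty_like(x)
    for i in range(n):
        for g in range(groups):
            sl = x[i, :, :, g * cg:(g + 1) * cg]
            out[i, :, :, g * cg:(g + 1) * cg] = (
                (sl - sl.mean()) / np.sqrt(sl.var() + eps))
    return out


class TestGroupNormalize:
    def _params(self, c, groups, eps=1e-5):
        return GroupNormParams(groups, np.ones(c), np.zeros(c), eps)

    def test_constant_group_maps_to_zeros(self):
        x = np.full((1, 4, 4, 2), 3.7)
        out = group_normalize(x, self._params(2, 1))
        np.testing.assert_allclose(out, 0.0, atol=1e-6)

    def test_hand_arithmetic_two_values(self):
        # one example, one group, values {1,3}: mu=2, sigma=1 -> {-1,+1}
        x = np.array([1.0, 3.0]).reshape(1, 1, 2, 1)
        out = group_normalize(x, self._params(1, 1, eps=1e-12)).ravel()
        np.testing.assert_allclose(out, [-1.0, 1.0], atol=1e-6)

    def test_batch_independence(self, rng):
        x = rng.standard_normal((2, 6, 6, 4))
        x[1] *= 10.0
        p = self._params(4, 2)
        joint = group_normalize(x, p)
        solo = group_normalize(x[1:2], p)
        np.testing.assert_allclose(joint[1], solo[0], atol=1e-12)

    @pytest.mark.parametrize("groups", [1, 2, 4])
    def test_matches_two_pass_oracle(self, rng, groups):
        x = rng.standard_normal((3, 5, 4, 4))
        out = group_normalize(x, self._params(4, groups))
        np.testing.assert_allclose(out, _gn_oracle(x, groups, 1e-5),
                                   atol=1e-10)

    def test_affine_applied_per_channel(self, rng):
        x = rng.standard_normal((1, 4, 4, 2))
        gamma, beta = np.array([2.0, 3.0]), np.array([-1.0, 5.0])
        base = group_normalize(x, self._params(2, 2))
        out = group_normalize(x, GroupNormParams(2, gamma, beta))
        np.testing.assert_allclose(out, gamma * base + beta, atol=1e-12)

    def test_rejects_indivisible_groups(self, rng):
        x = rng.standard_normal((1, 4, 4, 6))
        with pytest.raises(ValueError):
            group_normalize(x, self._params(6, 4))

    def test_group_fallback_when_fewer_channels(self):
        with pytest.warns(UserWarning):
            assert resolve_num_groups(32, 8) == 8
        assert resolve_num_groups(32, 64) == 32
        with pytest.raises(ValueError):
            resolve_num_groups(32, 48)


# ----------------------------------------------------------------------
# depthwise separable convolution
# ----------------------------------------------------------------------

def _direct_depthwise(x, dw):
    """Nested-loop depthwise convolution, same padding."""
    n, h, w, c = x.shape
    kh, kw = dw.shape[:2]
    pt, pl = (kh - 1) // 2, (kw - 1) // 2
    xp = np.pad(x, ((0, 0), (pt, kh - 1 - pt), (pl, kw - 1 - pl), (0, 0)))
    out = np.zeros_like(x)
    for b in range(n):
        for i in range(h):
            for j in range(w):
                for ch in range(c):
                    for a in range(kh):
                        for bb in range(kw):
                            out[b, i, j, ch] += (xp[b, i + a, j + bb, ch]
                                                 * dw[a, bb, ch, 0])
    return out


def _direct_pointwise(x, pw, bias):
    n, h, w, c = x.shape
    cout = pw.shape[3]
    out = np.zeros((n, h, w, cout))
    for b in range(n):
        for i in range(h):
            for j in range(w):
                for o in range(cout):
                    out[b, i, j, o] = (x[b, i, j] * pw[0, 0, :, o]).sum() + bias[o]
    return out


class TestDepthwiseSeparableConv:
    def test_identity_factorization(self, rng):
        x = rng.standard_normal((1, 6, 6, 3))
        dw = np.zeros((3, 3, 3, 1))
        dw[1, 1, :, 0] = 1.0                       # per-channel delta kernel
        pw = np.eye(3).reshape(1, 1, 3, 3)
        out = depthwise_separable_conv(x, dw, pw, np.zeros(3))
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_hand_arithmetic_single_pixel(self):
        # channels (2,3); dw centre weights (0.5,2) -> (1,6);
        # pw columns [[1,1],[1,-1]] -> (7,-5)
        x = np.array([2.0, 3.0]).reshape(1, 1, 1, 2)
        dw = np.zeros((3, 3, 2, 1))
        dw[1, 1, 0, 0] = 0.5
        dw[1, 1, 1, 0] = 2.0
        pw = np.array([[1.0, 1.0], [1.0, -1.0]]).reshape(1, 1, 2, 2)
        out = depthwise_separable_conv(x, dw, pw, np.zeros(2)).ravel()
        np.testing.assert_allclose(out, [7.0, -5.0], atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        x = rng.standard_normal((1, 8, 8, 4))
        dw = rng.standard_normal((3, 3, 4, 1))
        pw = rng.standard_normal((1, 1, 4, 5))
        bias = rng.standard_normal(5)
        fast = depthwise_separable_conv(x, dw, pw, bias)
        slow = _direct_pointwise(_direct_depthwise(x, dw), pw, bias)
        np.testing.assert_allclose(fast, slow, atol=1e-5)

    def test_linearity_without_bias(self, rng):
        x1 = rng.standard_normal((1, 5, 5, 3))
        x2 = rng.standard_normal((1, 5, 5, 3))
        dw = rng.standard_normal((3, 3, 3, 1))
        pw = rng.standard_normal((1, 1, 3, 2))
        f = lambda x: depthwise_separable_conv(x, dw, pw)
        np.testing.assert_allclose(f(2.0 * x1 - 3.0 * x2),
                                   2.0 * f(x1) - 3.0 * f(x2), atol=1e-9)

    def test_output_shape_is_function_of_input_shape(self, rng):
        for h, w in [(4, 4), (5, 7), (8, 3)]:
            x = rng.standard_normal((2, h, w, 3))
            out = depthwise_separable_conv(
                x, rng.standard_normal((3, 3, 3, 1)),
                rng.standard_normal((1, 1, 3, 6)))
            assert out.shape == (2, h, w, 6)

    def test_rejects_channel_mismatch(self, rng):
        x = rng.standard_normal((1, 4, 4, 3))
        with pytest.raises(ValueError):
            depthwise_separable_conv(x, np.zeros((3, 3, 2, 1)),
                                     np.zeros((1, 1, 3, 4)))
        with pytest.raises(ValueError):
            depthwise_separable_conv(x, np.zeros((3, 3, 3, 1)),
                                     np.zeros((1, 1, 2, 4)))


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_feature_map_and_weight_tensor_validation(seed):
    """Type wrappers accept any well-formed 4-D array and reject others."""
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(1, 5, size=4))
    FeatureMap(rng.standard_normal(shape))
    WeightTensor(rng.standard_normal(shape))
    with pytest.raises(ValueError):
        FeatureMap(rng.standard_normal(shape[:3]))
    with pytest.raises(ValueError):
        WeightTensor(rng.standard_normal(shape), eps=-1.0)
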