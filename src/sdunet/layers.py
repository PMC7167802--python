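"""Computational primitives: weight standardization, group normalization,
and depthwise separable convolution.

These are pure array-in/array-out functions on channel-last arrays
(batch N, height H, width W, channels C).  The trainable, differentiable
counterparts used inside networks live in :mod:`sdunet.nn`; both routes
share the same conventions and are cross-checked in the test suite.

Conventions
-----------
* Kernels are ``(kh, kw, in_channels, out_channels)``; depthwise kernels
  are ``(kh, kw, channels, 1)`` (channel multiplier fixed at 1).
* Weight standardization groups all weights feeding one output channel;
  for a depthwise kernel that group is the ``kh * kw`` taps of each
  channel's filter.  The standard deviation is the population one
  (divide by the count) and the guard ``eps`` is added to sigma itself,
  not to the variance.
* Group normalization pools statistics over (H, W, channels-in-group)
  within each example — never across the batch axis.
* Convolutions are stride 1 with "same" zero padding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad

__all__ = [
    "WeightTensor",
    "FeatureMap",
    "GroupNormParams",
    "weight_standardize",
    "group_normalize",
    "depthwise_separable_conv",
    "resolve_num_groups",
]

DEFAULT_EPS = 1e-5


@dataclass
class WeightTensor:
    """A 4-D convolution kernel with its numerical guard.

    ``values`` is ``(kh, kw, in_channels, out_channels)`` for standard and
    pointwise kernels, or ``(kh, kw, channels, 1)`` for depthwise kernels
    (``depthwise=True`` disambiguates the single-output-channel case).
    """

    values: np.ndarray
    eps: float = DEFAULT_EPS
    depthwise: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 4:
            raise ValueError(f"kernel must be 4-D, got {self.values.ndim}-D")
        if min(self.values.shape) < 1:
            raise ValueError("all kernel dimensions must be >= 1")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.depthwise and self.values.shape[3] != 1:
            raise ValueError("depthwise kernels have channel multiplier 1")


@dataclass
class FeatureMap:
    """A channel-last activation array (N, H, W, C)."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 4:
            raise ValueError(f"feature map must be 4-D, got {self.values.ndim}-D")
        if min(self.values.shape) < 1:
            raise ValueError("all feature-map dimensions must be >= 1")


@dataclass
class GroupNormParams:
    """Group count, per-channel affine, and variance guard for GN."""

    num_groups: int
    gamma: np.ndarray
    beta: np.ndarray
    eps: float = DEFAULT_EPS

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, dtype=np.float64).ravel()
        self.beta = np.asarray(self.beta, dtype=np.float64).ravel()
        if self.num_groups < 1:
            raise ValueError("num_groups must be >= 1")
        if self.gamma.shape != self.beta.shape:
            raise ValueError("gamma and beta must have equal length")
        if self.eps <= 0:
            raise ValueError("eps must be positive")


def _values(x, cls):
    return x.values if isinstance(x, cls) else np.asarray(x, dtype=np.float64)


def weight_standardize(w, eps: float = DEFAULT_EPS, depthwise: bool | None = None):
    """Standardize kernel weights per output channel: ``(W - mu) / (sigma + eps)``.

    For a standard kernel ``(kh, kw, cin, cout)`` the mean and population
    standard deviation are taken over ``(kh, kw, cin)`` for each output
    channel.  For a depthwise kernel ``(kh, kw, C, 1)`` each channel's
    ``kh x kw`` filter is standardized on its own.

    Returns an array of the input shape (or a :class:`WeightTensor` when
    given one).
    """
    wrap = isinstance(w, WeightTensor)
    if wrap:
        if depthwise is None:
            depthwise = w.depthwise
        eps = w.eps
        values = w.values
    else:
        values = np.asarray(w, dtype=np.float64)
        depthwise = bool(depthwise)
    if values.ndim != 4:
        raise ValueError(f"kernel must be 4-D, got {values.ndim}-D")
    if eps <= 0:
        raise ValueError("eps must be positive")

    axes = (0, 1) if depthwise else (0, 1, 2)
    mu = values.mean(axis=axes, keepdims=True)
    sigma = values.std(axis=axes, keepdims=True)  # population std
    out = (values - mu) / (sigma + eps)
    if wrap:
        return WeightTensor(out, eps=eps, depthwise=depthwise)
    return out


def resolve_num_groups(num_groups: int, channels: int) -> int:
    """Group count actually used for ``channels``: falls back to ``G = C``
    (instance normalization) with a warning when there are fewer channels
    than requested groups."""
    if channels < num_groups:
        warnings.warn(
            f"group count {num_groups} exceeds channel count {channels}; "
            f"falling back to G = C", stacklevel=2)
        return channels
    if channels % num_groups:
        raise ValueError(
            f"channel count {channels} not divisible by group count {num_groups}")
    return num_groups


def group_normalize(x, params: GroupNormParams):
    """Group-normalize a feature map per example.

    Statistics (mean, variance) are pooled over the spatial axes and the
    channels of each group, separately for every example in the batch;
    the per-channel affine ``gamma * xhat + beta`` is applied afterwards.
    """
    values = _values(x, FeatureMap)
    if values.ndim != 4:
        raise ValueError(f"feature map must be 4-D, got {values.ndim}-D")
    n, h, w, c = values.shape
    g = params.num_groups
    if params.eps <= 0:
        raise ValueError("eps must be positive")
    if c % g:
        raise ValueError(f"channel count {c} not divisible by group count {g}")
    if params.gamma.size != c:
        raise ValueError("gamma/beta length must equal the channel count")

    xg = values.reshape(n, h, w, g, c // g)
    mu = xg.mean(axis=(1, 2, 4), keepdims=True)
    var = xg.var(axis=(1, 2, 4), keepdims=True)
    xhat = ((xg - mu) / np.sqrt(var + params.eps)).reshape(n, h, w, c)
    out = params.gamma * xhat + params.beta
    return FeatureMap(out) if isinstance(x, FeatureMap) else out


def depthwise_separable_conv(x, dw, pw, bias=None):
    """Depthwise separable convolution: per-channel k x k stage, then a
    1 x 1 pointwise stage mixing channels, stride 1, same padding.

    ``dw`` is ``(k, k, C, 1)`` (or ``(k, k, C)``), ``pw`` is ``(1, 1, C, N)``,
    ``bias`` an optional length-N vector added after the pointwise stage.
    """
    xv = _values(x, FeatureMap)
    dwv = _values(dw, WeightTensor)
    pwv = _values(pw, WeightTensor)
    if xv.ndim != 4:
        raise ValueError("input must be (N, H, W, C)")
    if pwv.ndim != 4 or pwv.shape[:2] != (1, 1):
        raise ValueError("pointwise kernel must be (1, 1, C, N)")
    c = xv.shape[3]
    if (dwv.shape[2] if dwv.ndim >= 3 else -1) != c or pwv.shape[2] != c:
        raise ValueError(
            f"channel mismatch: input C={c}, depthwise C={dwv.shape[2] if dwv.ndim >= 3 else '?'}, "
            f"pointwise C={pwv.shape[2]}")
    mid = ad.depthwise_conv2d(xv, dwv).value
    out = ad.conv2d(mid, pwv, bias).value
    return FeatureMap(out) if isinstance(x, FeatureMap) else out
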