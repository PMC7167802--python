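"""Seeded synthetic datasets emulating the two benchmark regimes, plus the
shared preprocessing and augmentation steps.

Two generators are provided:

* :func:`generate_em_like` — grayscale electron-microscopy-style tiles: a
  seeded point process is turned into a space-partition tessellation whose
  walls (1–3 px wide, width jittered smoothly across the image) play the
  role of cell membranes.  Masks follow the "in-out" convention: interior
  pixels are 1 (white), membrane pixels 0 (black).  Images are smoothed
  interior intensity plus correlated texture with darker membranes.
* :func:`generate_brats_like` — 4-channel MRI-style slices with a 4-class
  label (background, edema, enhancing core, non-enhancing core).  Tumors
  are nested concentric ellipses — cores strictly inside the edema — with
  exact area ratios, so expected class frequencies are analytic
  (:func:`expected_class_priors`).  A configurable fraction of samples
  carries small tumors (under 2% of pixels).

Everything is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import AffineTransform, resize as _resize, warp

__all__ = [
    "SyntheticSample",
    "AugmentConfig",
    "generate_em_like",
    "generate_brats_like",
    "expected_class_priors",
    "preprocess",
    "augment",
    "one_hot",
    "DEFAULT_CELL_DENSITY",
]

# cells per pixel x 400: at the default an average cell covers ~570 px,
# giving a membrane fraction near 0.17 for 1-3 px walls
DEFAULT_CELL_DENSITY = 0.7

BRATS_CLASSES = ("background", "edema", "enhancing", "non_enhancing")
# linear scale of the nested core ellipses relative to the edema ellipse:
# enhancing core = 0.2 of the area, non-enhancing ring = 0.2, edema = 0.6
_CORE_INNER = np.sqrt(0.2)
_CORE_OUTER = np.sqrt(0.4)


@dataclass
class SyntheticSample:
    """One generated image with its label mask and provenance metadata."""

    image: np.ndarray            # (H, W, C) float
    mask: np.ndarray             # (H, W) integer class indices
    meta: dict = field(default_factory=dict)

    def one_hot_mask(self, num_classes: int | None = None) -> np.ndarray:
        return one_hot(self.mask, num_classes)


def one_hot(mask: np.ndarray, num_classes: int | None = None) -> np.ndarray:
    """Class-index image -> (H, W, K) one-hot float array."""
    mask = np.asarray(mask)
    k = int(mask.max()) + 1 if num_classes is None else num_classes
    return np.eye(k, dtype=np.float64)[mask]


@dataclass(frozen=True)
class AugmentConfig:
    """Spatial augmentation magnitudes (applied jointly to image + mask)."""

    horizontal_flip: float = 0.5
    zoom_range: tuple[float, float] = (0.9, 1.1)
    shift_range: tuple[float, float] = (0.1, 0.1)

    def __post_init__(self):
        if not 0.0 <= self.horizontal_flip <= 1.0:
            raise ValueError("flip probability must lie in [0, 1]")
        if min(self.zoom_range) <= 0:
            raise ValueError("zoom bounds must be positive")


# ----------------------------------------------------------------------
# EM-like tiles
# ----------------------------------------------------------------------

def _smooth_noise(rng, h, w, sigma):
    """Correlated noise field rescaled to [0, 1]."""
    f = gaussian_filter(rng.standard_normal((h, w)), sigma)
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo) if hi > lo else np.zeros_like(f)

def _sample_points(rng, h, w, k, min_sep):
    """Up to k points with pairwise separation >= min_sep (rejection)."""
    pts = []
    for _ in range(40 * k):
        cand = rng.uniform([0, 0], [h, w])
        if all((cand[0] - p[0]) ** 2 + (cand[1] - p[1]) ** 2 >= min_sep ** 2
               for p in pts):
            pts.append(cand)
            if len(pts) == k:
                break
    return np.array(pts)


def generate_em_like(n: int, H: int, W: int, seed: int,
                     cell_density: float = DEFAULT_CELL_DENSITY,
                     ) -> list[SyntheticSample]:
    """EM-style grayscale tiles with binary in-out membrane masks.

    ``cell_density`` in (0, 1] scales the expected cell count
    (``density * H * W / 400`` cells); walls between tessellation cells
    are 1–3 px wide with the width varying smoothly across the tile.
    """
    if n < 1 or H < 1 or W < 1:
        raise ValueError("n, H, W must be positive")
    if not 0.0 < cell_density <= 1.0:
        raise ValueError("cell_density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    k = max(2, round(cell_density * H * W / 400))
    if k < 2:
        raise ValueError("fewer than 2 tessellation seed points")
    min_sep = 0.7 * np.sqrt(H * W / k)

    samples = []
    ii, jj = np.mgrid[0:H, 0:W]
    for _ in range(n):
        pts = _sample_points(rng, H, W, k, min_sep)
        if len(pts) < 2:
            raise ValueError("degenerate tessellation: fewer than 2 points")
        # distances of every pixel to every seed point
        d = np.sqrt((ii[..., None] - pts[:, 0]) ** 2
                    + (jj[..., None] - pts[:, 1]) ** 2)
        d.sort(axis=-1)
        width = 1.0 + 2.0 * _smooth_noise(rng, H, W, sigma=max(H, W) / 8)
        wall = (d[..., 1] - d[..., 0]) < width
        mask = (~wall).astype(np.int64)

        texture = _smooth_noise(rng, H, W, sigma=3.0)
        grain = rng.standard_normal((H, W)) * 0.04
        img = 0.30 + 0.40 * mask + 0.22 * texture + grain
        img = np.clip(img, 0.0, 1.0)[..., None]
        samples.append(SyntheticSample(
            image=img, mask=mask,
            meta={"kind": "em_like", "seed": seed,
                  "cell_density": cell_density, "n_cells": len(pts)}))
    return samples


# ----------------------------------------------------------------------
# BRATs-like slices
# ----------------------------------------------------------------------

def expected_class_priors(tumor_area_range=(0.04, 0.12),
                          small_tumor_area_range=(0.002, 0.02),
                          small_tumor_fraction=0.3) -> dict:
    """Expected pixel fraction of each class under the generator defaults."""
    mean_area = (small_tumor_fraction * np.mean(small_tumor_area_range)
                 + (1 - small_tumor_fraction) * np.mean(tumor_area_range))
    return {
        "background": 1.0 - mean_area,
        "edema": 0.6 * mean_area,
        "enhancing": 0.2 * mean_area,
        "non_enhancing": 0.2 * mean_area,
    }


def _ellipse_mask(h, w, center, axes, theta):
    ii, jj = np.mgrid[0:h, 0:w]
    y = ii - center[0]
    x = jj - center[1]
    c, s = np.cos(theta), np.sin(theta)
    u = c * y + s * x
    v = -s * y + c * x
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def generate_brats_like(n: int, H: int, W: int, seed: int,
                        tumor_area_range=(0.04, 0.12),
                        small_tumor_area_range=(0.002, 0.02),
                        small_tumor_fraction: float = 0.3,
                        ) -> list[SyntheticSample]:
    """4-channel MRI-style slices with nested 4-class tumor labels.

    Labels: 0 background, 1 edema, 2 enhancing core, 3 non-enhancing
    core; the cores are concentric ellipses strictly inside the edema
    ellipse with fixed area ratios 0.2 / 0.2 / 0.6.  The four channels are
    modality surrogates with distinct contrast responses to the tumor
    compartments (T1-like: dark cores; T1-Gd-like: bright enhancing;
    T2-like: bright edema; FLAIR-like: bright edema + cores).
    """
    if n < 1 or H < 1 or W < 1:
        raise ValueError("n, H, W must be positive")
    if not 0.0 <= small_tumor_fraction <= 1.0:
        raise ValueError("small_tumor_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(n):
        small = rng.random() < small_tumor_fraction
        lo, hi = small_tumor_area_range if small else tumor_area_range
        frac = rng.uniform(lo, hi)
        area = frac * H * W
        r = np.sqrt(area / np.pi)
        q = rng.uniform(0.6, 1.0)           # aspect ratio
        a, b = r / np.sqrt(q), r * np.sqrt(q)
        theta = rng.uniform(0, np.pi)
        margin = max(a, b)
        cy = rng.uniform(margin, H - margin) if H > 2 * margin else H / 2
        cx = rng.uniform(margin, W - margin) if W > 2 * margin else W / 2

        edema = _ellipse_mask(H, W, (cy, cx), (a, b), theta)
        outer = _ellipse_mask(H, W, (cy, cx),
                              (a * _CORE_OUTER, b * _CORE_OUTER), theta)
        inner = _ellipse_mask(H, W, (cy, cx),
                              (a * _CORE_INNER, b * _CORE_INNER), theta)
        mask = np.zeros((H, W), dtype=np.int64)
        mask[edema] = 1
        mask[outer] = 3          # non-enhancing ring
        mask[inner] = 2          # enhancing core

        tissue = 0.35 + 0.3 * _smooth_noise(rng, H, W, sigma=6.0)
        edema_all = edema.astype(float)          # whole tumor extent
        cores = (outer).astype(float)
        enh = inner.astype(float)
        channels = [
            tissue - 0.25 * cores,                        # T1-like
            tissue + 0.45 * enh,                          # T1-Gd-like
            tissue + 0.35 * edema_all,                    # T2-like
            tissue + 0.30 * edema_all + 0.15 * cores,     # FLAIR-like
        ]
        img = np.stack(channels, axis=-1)
        img += rng.standard_normal(img.shape) * 0.03
        img = np.clip(img, 0.0, 1.0)
        samples.append(SyntheticSample(
            image=img, mask=mask,
            meta={"kind": "brats_like", "seed": seed, "small_tumor": small,
                  "tumor_fraction": frac}))
    return samples


# ----------------------------------------------------------------------
# preprocessing & augmentation
# ----------------------------------------------------------------------

def preprocess(image, mask, target_size, crop=None):
    """Center-crop (optional), resize, and standardize an image/mask pair.

    ``crop`` is an optional (h, w) center-crop applied before resizing to
    ``target_size``; the image is resized bilinearly and standardized per
    channel to zero mean, unit variance (constant channels map to zeros),
    the mask with nearest-neighbour interpolation.
    """
    img = np.asarray(image, dtype=np.float64)
    msk = np.asarray(mask)
    squeeze = img.ndim == 2
    if squeeze:
        img = img[..., None]
    if img.shape[:2] != msk.shape[:2]:
        raise ValueError("image and mask spatial shapes differ")

    if crop is not None:
        ch, cw = crop
        h, w = img.shape[:2]
        if ch > h or cw > w:
            raise ValueError(f"crop {crop} larger than source {(h, w)}")
        oy, ox = (h - ch) // 2, (w - cw) // 2
        img = img[oy:oy + ch, ox:ox + cw]
        msk = msk[oy:oy + ch, ox:ox + cw]

    th, tw = target_size
    if (th, tw) != img.shape[:2]:
        img = _resize(img, (th, tw), order=1, mode="reflect",
                      anti_aliasing=img.shape[0] > th, preserve_range=True)
        msk = _resize(msk.astype(np.float64), (th, tw), order=0,
                      mode="reflect", anti_aliasing=False,
                      preserve_range=True).round().astype(msk.dtype)

    mu = img.mean(axis=(0, 1), keepdims=True)
    sd = img.std(axis=(0, 1), keepdims=True)
    img = np.where(sd > 0, (img - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    if squeeze:
        img = img[..., 0]
    return img, msk


def augment(sample: SyntheticSample, cfg: AugmentConfig,
            seed: int) -> SyntheticSample:
    """Seeded horizontal flip + zoom + shift, applied jointly to image and
    mask (nearest-neighbour for the mask, reflection fill)."""
    rng = np.random.default_rng(seed)
    img = sample.image.copy()
    msk = sample.mask.copy()

    flipped = rng.random() < cfg.horizontal_flip
    if flipped:
        img = img[:, ::-1]
        msk = msk[:, ::-1]

    zoom = rng.uniform(*cfg.zoom_range)
    h, w = msk.shape
    dy = rng.uniform(-cfg.shift_range[0], cfg.shift_range[0]) * h
    dx = rng.uniform(-cfg.shift_range[1], cfg.shift_range[1]) * w

    if zoom != 1.0 or dy or dx:
        # output -> input mapping about the image centre, then shift
        cy, cx = (h - 1) / 2, (w - 1) / 2
        tform = (AffineTransform(translation=(-cx, -cy))
                 + AffineTransform(scale=1.0 / zoom)
                 + AffineTransform(translation=(cx - dx, cy - dy)))
        img = warp(img, tform, order=1, mode="reflect", preserve_range=True)
        msk = warp(msk.astype(np.float64), tform, order=0, mode="reflect",
                   preserve_range=True).round().astype(sample.mask.dtype)

    meta = dict(sample.meta)
    meta["augment"] = {"seed": seed, "flipped": bool(flipped),
                       "zoom": float(zoom), "shift": (float(dy), float(dx))}
    return SyntheticSample(image=img, mask=msk, meta=meta)
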