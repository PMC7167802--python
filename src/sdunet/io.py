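"""Readers and writers for image/mask stacks.

EM-style data travels as multi-page TIFF pairs (``images.tif`` float32 in
[0, 1], ``masks.tif`` uint8 in-out labels); BRATs-style data as per-slice
PNG files (one grayscale PNG per channel plus a class-index mask PNG).
Every written directory carries a ``manifest.json`` with the generator
parameters and seeds.  NIfTI volumes can be ingested as 2-D slices when
nibabel is installed (optional extra).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .synthetic_data import SyntheticSample

__all__ = [
    "save_em_stack",
    "load_em_stack",
    "save_brats_slices",
    "load_brats_slices",
    "load_nifti_slices",
]


def _write_manifest(path: Path, samples: list[SyntheticSample], kind: str):
    manifest = {
        "kind": kind,
        "n": len(samples),
        "meta": [s.meta for s in samples],
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def save_em_stack(samples: list[SyntheticSample], out_dir) -> Path:
    """Write samples as images.tif / masks.tif multi-page stacks."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    images = np.stack([s.image[..., 0] for s in samples]).astype(np.float32)
    masks = np.stack([s.mask for s in samples]).astype(np.uint8)
    tifffile.imwrite(out / "images.tif", images, photometric="minisblack")
    tifffile.imwrite(out / "masks.tif", masks, photometric="minisblack")
    _write_manifest(out, samples, "em_like")
    return out


def load_em_stack(in_dir) -> list[SyntheticSample]:
    src = Path(in_dir)
    images = tifffile.imread(src / "images.tif")
    masks = tifffile.imread(src / "masks.tif")
    if images.ndim == 2:
        images, masks = images[None], masks[None]
    meta = [{}] * len(images)
    manifest = src / "manifest.json"
    if manifest.exists():
        meta = json.loads(manifest.read_text()).get("meta", meta)
    return [SyntheticSample(image=img[..., None].astype(np.float64),
                            mask=msk.astype(np.int64), meta=m)
            for img, msk, m in zip(images, masks, meta)]


def save_brats_slices(samples: list[SyntheticSample], out_dir) -> Path:
    """Write samples as per-slice grayscale PNGs (one per channel) and a
    class-index mask PNG."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(samples):
        for c in range(s.image.shape[-1]):
            arr = np.clip(s.image[..., c] * 255, 0, 255).astype(np.uint8)
            Image.fromarray(arr).save(out / f"slice{i:04d}_ch{c}.png")
        Image.fromarray(s.mask.astype(np.uint8)).save(
            out / f"slice{i:04d}_mask.png")
    _write_manifest(out, samples, "brats_like")
    return out


def load_brats_slices(in_dir) -> list[SyntheticSample]:
    src = Path(in_dir)
    mask_files = sorted(src.glob("slice*_mask.png"))
    if not mask_files:
        raise FileNotFoundError(f"no slice*_mask.png files in {src}")
    meta = [{}] * len(mask_files)
    manifest = src / "manifest.json"
    if manifest.exists():
        meta = json.loads(manifest.read_text()).get("meta", meta)
    samples = []
    for mf, m in zip(mask_files, meta):
        stem = mf.name.replace("_mask.png", "")
        chans = sorted(src.glob(f"{stem}_ch*.png"))
        img = np.stack([np.asarray(Image.open(c), dtype=np.float64) / 255.0
                        for c in chans], axis=-1)
        mask = np.asarray(Image.open(mf), dtype=np.int64)
        samples.append(SyntheticSample(image=img, mask=mask, meta=m))
    return samples


def load_nifti_slices(image_path, mask_path=None, axis: int = 2):
    """Slice a NIfTI volume into 2-D samples along ``axis``.

    Requires nibabel (install the ``nifti`` extra).
    """
    try:
        import nibabel as nib
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("NIfTI ingestion requires nibabel "
                          "(pip install sdunet[nifti])") from exc
    vol = np.asarray(nib.load(str(image_path)).dataobj, dtype=np.float64)
    msk = None
    if mask_path is not None:
        msk = np.asarray(nib.load(str(mask_path)).dataobj)
    vol = np.moveaxis(vol, axis, 0)
    if msk is not None:
        msk = np.moveaxis(msk, axis, 0)
    samples = []
    for i in range(vol.shape[0]):
        img = vol[i]
        if img.ndim == 2:
            img = img[..., None]
        mask = (msk[i].astype(np.int64) if msk is not None
                else np.zeros(img.shape[:2], dtype=np.int64))
        samples.append(SyntheticSample(image=img, mask=mask,
                                       meta={"kind": "nifti", "index": i}))
    return samples
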