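"""Readers and writers for the on-disk sample formats, plus 3D patch
sampling.

2D samples are PNG pairs: a 16-bit grayscale (or 8-bit RGB) image and an
8-bit paletted label mask.  3D samples are NIfTI volumes with the voxel
spacing in the header; the in-memory axis order is (H, W, D).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import List, Optional, Tuple

import nibabel as nib
import numpy as np
from PIL import Image

from .phantoms import SegmentationSample

__all__ = ["write_mask_png", "write_sample_2d", "read_sample_2d",
           "write_volume", "read_volume", "sample_patches", "normalize_image"]

# a small categorical palette so label PNGs are viewable
_PALETTE = np.array([[0, 0, 0], [230, 60, 60], [60, 180, 90], [70, 110, 240],
                     [240, 200, 60], [170, 80, 200], [80, 210, 220],
                     [240, 140, 60], [150, 150, 150]], np.uint8)


def write_mask_png(path, mask) -> None:
    """Write integer labels as a paletted 8-bit PNG (losslessly: the pixel
    values are the palette indices, i.e. the labels)."""
    arr = np.asarray(mask).astype(np.uint8)
    pal_img = Image.fromarray(arr)       # mode 'L'
    pal = np.zeros((256, 3), np.uint8)
    pal[: len(_PALETTE)] = _PALETTE
    pal_img.putpalette(pal.flatten())    # switches to 'P', keeps values
    pal_img.save(path)


def write_sample_2d(image_path, mask_path, sample: SegmentationSample) -> None:
    img = np.asarray(sample.image)
    if img.ndim != 2:
        raise ValueError("2D writer expects a single-channel (H, W) image")
    arr16 = np.round(np.clip(img, 0, 1) * 65535.0).astype(np.uint16)
    Image.fromarray(arr16).save(image_path)  # uint16 -> 16-bit grayscale
    write_mask_png(mask_path, sample.mask)


def read_sample_2d(image_path, mask_path) -> SegmentationSample:
    """Read an image/mask pair; the image is normalized to [0, 1] and the
    original intensity range recorded in ``meta``."""
    try:
        pil = Image.open(image_path)
        pil.load()
    except Exception as exc:
        raise ValueError(f"cannot read image {image_path}: {exc}") from exc
    if pil.mode in ("I;16", "I"):
        arr = np.asarray(pil, np.float64)
        scale = 65535.0
    elif pil.mode in ("L",):
        arr = np.asarray(pil, np.float64)
        scale = 255.0
    elif pil.mode in ("RGB", "RGBA"):
        arr = np.asarray(pil.convert("RGB"), np.float64)
        scale = 255.0
    else:
        raise ValueError(f"unsupported image mode {pil.mode!r}")
    img = (arr / scale).astype(np.float32)
    mask = np.asarray(Image.open(mask_path)).astype(np.uint8)
    if mask.ndim != 2:
        raise ValueError("mask must be single-channel")
    if img.shape[:2] != mask.shape:
        raise ValueError(
            f"image {img.shape[:2]} and mask {mask.shape} shapes disagree")
    return SegmentationSample(img, mask, (1.0, 1.0),
                              meta={"orig_scale": scale})


def write_volume(path, array, spacing) -> None:
    array = np.asarray(array)
    spacing = tuple(float(s) for s in spacing)
    affine = np.diag(list(spacing) + [1.0])
    dtype = np.uint8 if array.dtype == np.uint8 else np.float32
    img = nib.Nifti1Image(array.astype(dtype), affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def read_volume(path) -> Tuple[np.ndarray, Tuple[float, ...]]:
    """Load a volume as ((H, W, D) array, spacing); a header without usable
    spacing falls back to (1, 1, 1) with a warning."""
    try:
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj)
    except Exception as exc:
        raise ValueError(f"cannot read volume {path}: {exc}") from exc
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 or not np.isfinite(z) for z in zooms):
        warnings.warn(f"{path}: no usable spacing in header, assuming (1,1,1)")
        zooms = (1.0, 1.0, 1.0)
    return arr, zooms


def normalize_image(arr, mode="minmax"):
    """Intensity normalization: per-image min-max (phantom default) or
    z-score (for real volumes)."""
    arr = np.asarray(arr, np.float32)
    if mode == "minmax":
        lo, hi = float(arr.min()), float(arr.max())
        return (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    if mode == "zscore":
        sd = float(arr.std())
        return (arr - float(arr.mean())) / sd if sd > 0 else np.zeros_like(arr)
    raise ValueError(f"unknown normalization {mode!r}")


def sample_patches(volume, mask, patch_size, n, seed, fg_bias=0.5
                   ) -> List[Tuple[np.ndarray, np.ndarray, Tuple[int, ...]]]:
    """Draw ``n`` random patches; a ``fg_bias`` fraction is centered on a
    random foreground voxel (clamped to the grid).  Deterministic in seed.

    Returns (image_patch, mask_patch, corner) triples.
    """
    volume, mask = np.asarray(volume), np.asarray(mask)
    patch = tuple(int(p) for p in patch_size)
    if any(p > e for p, e in zip(patch, volume.shape)):
        raise ValueError(
            f"patch {patch} exceeds volume extent {volume.shape}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    fg = np.argwhere(mask > 0)
    out = []
    for _ in range(n):
        if len(fg) and rng.uniform() < fg_bias:
            center = fg[rng.integers(len(fg))]
            corner = [int(np.clip(c - p // 2, 0, e - p))
                      for c, p, e in zip(center, patch, volume.shape)]
        else:
            corner = [int(rng.integers(0, e - p + 1))
                      for p, e in zip(patch, volume.shape)]
        sl = tuple(slice(c, c + p) for c, p in zip(corner, patch))
        out.append((volume[sl], mask[sl], tuple(corner)))
    return out
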