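"""Seeded multi-class anatomical phantoms in 2D and 3D.

Each foreground class is a perturbed-radius star blob: an ellipse (2D) or
ellipsoid (3D) whose radius is modulated by low-order angular harmonics,
giving compact-to-elongated irregular targets.  The rendered image is the
per-class contrast map, optionally blurred at the boundaries with a
Gaussian kernel and corrupted with additive Gaussian noise, then clipped to
[0, 1] and quantized to the 16-bit grid (so file round-trips are exact).
Everything is a deterministic function of ``(spec, seed)``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

__all__ = ["PhantomSpec", "SegmentationSample", "generate_phantom",
           "make_dataset", "load_manifest"]


@dataclass
class PhantomSpec:
    """Study conditions for phantom generation.

    ``size_range`` is the blob base radius as a fraction of the smallest
    grid extent; grid extents must be model-legal (in-plane divisible by 32,
    slice axis divisible by 2 in 3D).
    """

    dim: int = 2
    shape: Tuple[int, ...] = (64, 64)
    num_classes: int = 4              # including background label 0
    size_range: Tuple[float, float] = (0.12, 0.3)
    blur_sigma: float = 1.0
    noise_sigma: float = 0.05
    contrasts: Optional[Tuple[float, ...]] = None
    overlap: str = "disjoint"         # or "nested"
    spacing: Optional[Tuple[float, ...]] = None

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if self.dim not in (2, 3) or len(self.shape) != self.dim:
            raise ValueError("dim/shape mismatch")
        inplane = self.shape[:2]
        if any(e % 32 for e in inplane):
            raise ValueError("in-plane extents must be divisible by 32")
        if self.dim == 3 and self.shape[2] % 2:
            raise ValueError("slice extent must be divisible by 2")
        lo, hi = self.size_range
        if not (0 < lo <= hi < 0.9):
            raise ValueError("size_range must lie in (0, 0.9)")
        if self.num_classes < 2:
            raise ValueError("need background plus at least one class")
        if self.overlap not in ("disjoint", "nested"):
            raise ValueError(f"unknown overlap policy {self.overlap!r}")
        if self.contrasts is None:
            # background dark, classes spread over the remaining range
            k = self.num_classes - 1
            self.contrasts = tuple([0.1] + [0.3 + 0.6 * i / max(k - 1, 1)
                                            for i in range(k)])
        if len(self.contrasts) != self.num_classes:
            raise ValueError("need one contrast per class (incl. background)")
        if self.spacing is None:
            self.spacing = (1.0,) * self.dim
        self.spacing = tuple(float(s) for s in self.spacing)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class SegmentationSample:
    image: np.ndarray                 # float32 in [0, 1], (spatial...)
    mask: np.ndarray                  # uint8 labels, same grid
    spacing: Tuple[float, ...]
    meta: dict = field(default_factory=dict)


def _star_blob(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Rasterize one random star-shaped blob as a boolean mask."""
    shape = np.array(spec.shape, float)
    lo, hi = spec.size_range
    base_r = rng.uniform(lo, hi) * shape.min()
    center = np.array([rng.uniform(0.2 * e, 0.8 * e) for e in shape])
    # anisotropic axis scaling in [0.5, 1.6] makes elongated targets
    axis_scale = rng.uniform(0.6, 1.6, size=spec.dim)
    grids = np.meshgrid(*[np.arange(e) for e in spec.shape], indexing="ij")
    delta = [(g - c) / s for g, c, s in zip(grids, center, axis_scale)]
    rr = np.sqrt(sum(d * d for d in delta)) + 1e-9
    theta = np.arctan2(delta[1], delta[0])
    wobble = np.zeros_like(rr)
    for m in range(2, 5):
        wobble += rng.uniform(0, 0.25) / (m - 1) * np.cos(
            m * theta + rng.uniform(0, 2 * np.pi))
    if spec.dim == 3:
        phi = np.arccos(np.clip(delta[2] / rr, -1, 1))
        for m in range(2, 4):
            wobble += rng.uniform(0, 0.2) / (m - 1) * np.cos(
                m * phi + rng.uniform(0, 2 * np.pi))
    radius = base_r * (1.0 + wobble)
    return rr <= radius


def generate_phantom(spec: PhantomSpec, seed: int) -> SegmentationSample:
    """Deterministic multi-class phantom for a (spec, seed) pair."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    mask = np.zeros(spec.shape, np.uint8)
    for cls in range(1, spec.num_classes):
        placed = False
        blob = None
        for attempt in range(60):
            blob = _star_blob(spec, rng)
            if not blob.any():
                continue
            if spec.overlap == "nested":
                placed = True
                break
            free = blob & (mask == 0)
            # accept an essentially clean placement
            if free.sum() >= 0.98 * blob.sum():
                blob = free
                placed = free.any()
                if placed:
                    break
        if not placed and blob is not None and spec.overlap == "disjoint":
            blob = blob & (mask == 0)
            placed = blob.any()
        if not placed:
            # guarantee presence: claim a tiny ball around a free voxel
            free_idx = np.argwhere(mask == 0)
            c = free_idx[rng.integers(len(free_idx))]
            grids = np.meshgrid(*[np.arange(e) for e in spec.shape],
                                indexing="ij")
            rr = np.sqrt(sum((g - ci) ** 2 for g, ci in zip(grids, c)))
            blob = (rr <= 2.0) & (mask == 0)
        mask[blob] = cls

    img = np.asarray(spec.contrasts, np.float64)[mask]
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma)
    if spec.noise_sigma > 0:
        img = img + spec.noise_sigma * rng.standard_normal(img.shape)
    img = np.clip(img, 0.0, 1.0)
    img = np.round(img * 65535.0) / 65535.0
    return SegmentationSample(img.astype(np.float32), mask,
                              spec.spacing,
                              meta={"seed": int(seed),
                                    "spec_hash": spec.hash()})


def _sample_seed(base_seed: int, i: int) -> int:
    # stable per-sample seed, kept below 2**31
    h = hashlib.sha256(f"{base_seed}:{i}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def make_dataset(spec: PhantomSpec, n: int, seed: int, out_dir,
                 train_ratio: float = 0.8) -> dict:
    """Write ``n`` phantoms plus a JSON manifest with a train/val split.

    2D samples go to image/mask PNG pairs, 3D samples to NIfTI volumes with
    the spacing in the header.  Returns the manifest dict.
    """
    from . import io as eio
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i in range(n):
        s = _sample_seed(seed, i)
        sample = generate_phantom(spec, s)
        stem = f"case_{i:04d}"
        if spec.dim == 2:
            img_p = out_dir / f"{stem}_img.png"
            msk_p = out_dir / f"{stem}_mask.png"
            eio.write_sample_2d(img_p, msk_p, sample)
        else:
            img_p = out_dir / f"{stem}_img.nii"
            msk_p = out_dir / f"{stem}_mask.nii"
            eio.write_volume(img_p, sample.image, sample.spacing)
            eio.write_volume(msk_p, sample.mask, sample.spacing)
        entries.append({"id": stem, "seed": s,
                        "image": img_p.name, "mask": msk_p.name})
    n_train = int(round(n * train_ratio))
    manifest = {
        "spec": asdict(spec),
        "seed": int(seed),
        "train_ratio": train_ratio,
        "samples": entries,
        "split": {"train": [e["id"] for e in entries[:n_train]],
                  "val": [e["id"] for e in entries[n_train:]]},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def load_manifest(path) -> tuple:
    """Read a dataset manifest; returns (manifest, directory, spec)."""
    path = Path(path)
    if path.is_dir():
        path = path / "manifest.json"
    with open(path) as fh:
        manifest = json.load(fh)
    spec = PhantomSpec(**{k: tuple(v) if isinstance(v, list) else v
                          for k, v in manifest["spec"].items()})
    return manifest, path.parent, spec
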