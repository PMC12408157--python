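"""Nearest-neighbor resizing (functional, with explicit adjoint)."""

from __future__ import annotations

import numpy as np

__all__ = ["nearest_indices", "nearest_resize", "nearest_resize_adjoint"]


def nearest_indices(src: int, dst: int) -> np.ndarray:
    """Source index for each destination index (floor rule, as used by
    framework-style ``interpolate(mode='nearest')``)."""
    return (np.arange(dst) * src // dst).astype(np.intp)


def nearest_resize(x: np.ndarray, target) -> np.ndarray:
    """Resize the spatial axes (all but the first two) of ``x`` to ``target``."""
    spatial = x.shape[2:]
    if len(target) != len(spatial):
        raise ValueError("target rank mismatch")
    for axis, (s, t) in enumerate(zip(spatial, target)):
        if t != s:
            x = np.take(x, nearest_indices(s, t), axis=axis + 2)
    return x


def nearest_resize_adjoint(gy: np.ndarray, src_spatial) -> np.ndarray:
    """Adjoint of :func:`nearest_resize` (scatter-add back to the source grid)."""
    for axis, s in enumerate(src_spatial):
        t = gy.shape[axis + 2]
        if t == s:
            continue
        idx = nearest_indices(s, t)
        moved = np.moveaxis(gy, axis + 2, 0)
        out = np.zeros((s,) + moved.shape[1:], gy.dtype)
        np.add.at(out, idx, moved)
        gy = np.moveaxis(out, 0, axis + 2)
    return gy
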