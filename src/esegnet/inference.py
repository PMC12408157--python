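"""Whole-image (2D) and sliding-window (3D) inference.

Inputs whose extents are not model-legal are edge-padded up to the required
divisibility and the padding is cropped from the output, so the predicted
label map always matches the input grid.  3D volumes are tiled with
overlapping windows whose logits are averaged before the argmax; ties in
the argmax go to the lowest class index.
"""

from __future__ import annotations

import itertools
from typing import Optional, Tuple

import numpy as np

__all__ = ["pad_to_legal", "predict_image", "predict_volume",
           "sliding_window_logits"]


def pad_to_legal(arr, divisors, min_extent=None):
    """Edge-pad trailing spatial axes of (C, spatial...) up to divisibility
    (and optionally up to a minimum extent).  Returns (padded, pads)."""
    spatial = arr.shape[1:]
    pads = []
    for i, (e, d) in enumerate(zip(spatial, divisors)):
        target = ((e + d - 1) // d) * d
        if min_extent is not None:
            target = max(target, min_extent[i])
        pads.append((0, target - e))
    padded = np.pad(arr, [(0, 0)] + pads, mode="edge")
    return padded, pads


def _crop(arr, pads, ndim_spatial):
    sl = tuple(slice(None) for _ in range(arr.ndim - ndim_spatial)) + tuple(
        slice(0, arr.shape[arr.ndim - ndim_spatial + i] - p[1])
        for i, p in enumerate(pads))
    return arr[sl]


def _as_channel_first(image, in_channels):
    img = np.asarray(image, np.float32)
    if img.ndim == 2:
        img = img[None]
    elif img.ndim == 3 and img.shape[-1] in (3, 4):
        img = np.moveaxis(img[..., :3], -1, 0)
    if img.shape[0] == 1 and in_channels == 3:
        img = np.repeat(img, 3, axis=0)
    if img.shape[0] != in_channels:
        raise ValueError(
            f"image has {img.shape[0]} channels, model expects {in_channels}")
    return img


def predict_image(model, image) -> np.ndarray:
    """Label map for a single 2D image (H, W) or (H, W, 3)."""
    img = _as_channel_first(image, model.encoder.in_channels)
    padded, pads = pad_to_legal(img, model.required_divisors())
    labels = model.predict_labels(padded[None])[0]
    return _crop(labels, pads, 2).astype(np.uint8)


def _window_starts(extent, window, step):
    if window >= extent:
        return [0]
    starts = list(range(0, extent - window + 1, max(step, 1)))
    if starts[-1] != extent - window:
        starts.append(extent - window)
    return starts


def sliding_window_logits(model, volume_cf, window, overlap=0.5) -> np.ndarray:
    """Overlap-averaged logits over a channel-first volume (C, H, W, D)."""
    window = tuple(int(w) for w in window)
    spatial = volume_cf.shape[1:]
    steps = [max(1, int(w * (1.0 - overlap))) for w in window]
    starts = [_window_starts(e, w, s)
              for e, w, s in zip(spatial, window, steps)]
    logits = np.zeros((model.num_classes,) + spatial, np.float64)
    counts = np.zeros(spatial, np.float64)
    was_training = model.training
    model.eval()
    try:
        for corner in itertools.product(*starts):
            sl = tuple(slice(c, c + w) for c, w in zip(corner, window))
            out = model.forward(volume_cf[(slice(None),) + sl][None])[0]
            logits[(slice(None),) + sl] += out
            counts[sl] += 1.0
    finally:
        model.train(was_training)
    return logits / counts[None]


def predict_volume(model, volume, window=None, overlap=0.5) -> np.ndarray:
    """Label map for a (H, W, D) volume via sliding-window inference.

    ``window=None`` uses the whole (padded-to-legal) volume as one window,
    which is identical to a single forward pass.
    """
    vol = np.asarray(volume, np.float32)[None]  # single channel
    div = model.required_divisors()
    padded, pads = pad_to_legal(vol, div)
    if window is None:
        window = padded.shape[1:]
    window = tuple(min(int(w), e) for w, e in zip(window, padded.shape[1:]))
    if any(w % d for w, d in zip(window, div)):
        raise ValueError(
            f"window {window} must be divisible by {div} per axis")
    logits = sliding_window_logits(model, padded, window, overlap)
    labels = np.argmax(logits, axis=0)
    return _crop(labels, pads, 3).astype(np.uint8)
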