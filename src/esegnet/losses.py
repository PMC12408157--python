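"""Training losses: soft Dice, cross-entropy, and their weighted compound.

The compound loss is ``w_dice * L_dice + w_ce * L_ce`` with default weights
(0.6, 0.4) for 2D models and (1, 1) for 3D models.  All functions return
both the scalar loss and the analytic gradient with respect to the logits
(or probabilities), so they plug straight into the layer-graph backward
pass.
"""

from __future__ import annotations

import numpy as np

__all__ = ["softmax", "one_hot", "dice_loss", "cross_entropy",
           "combined_loss", "CombinedLoss", "default_loss_weights"]


def default_loss_weights(dim: int):
    return (0.6, 0.4) if dim == 2 else (1.0, 1.0)


def softmax(z, axis=1):
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def one_hot(labels, num_classes):
    """(N, spatial...) integer labels -> (N, C, spatial...) one-hot floats."""
    labels = np.asarray(labels)
    oh = np.zeros((labels.shape[0], num_classes) + labels.shape[1:],
                  np.float64)
    idx = np.indices(labels.shape)
    oh[(idx[0], labels) + tuple(idx[1:])] = 1.0
    return oh


def _check_shapes(probs, target):
    if probs.shape[0] != target.shape[0] or probs.shape[2:] != target.shape[1:]:
        raise ValueError(
            f"probs {probs.shape} incompatible with target {target.shape}")


def dice_loss(probs, target, *, eps=1e-5, include_empty=False,
              with_grad=False):
    """1 - mean per-class soft Dice.

    ``probs`` are per-pixel class probabilities (softmax upstream), ``target``
    integer labels.  By default the mean runs over the classes present in the
    target; ``include_empty=True`` averages over all channels (absent classes
    then contribute a near-zero Dice term, guarded by ``eps``).
    """
    _check_shapes(probs, target)
    ncls = probs.shape[1]
    t = one_hot(target, ncls)
    red = (0,) + tuple(range(2, probs.ndim))
    inter = (probs * t).sum(axis=red)
    psum = probs.sum(axis=red)
    tsum = t.sum(axis=red)
    num = 2.0 * inter + eps
    den = psum + tsum + eps
    dice = num / den
    counted = np.ones(ncls, bool) if include_empty else tsum > 0
    k = max(int(counted.sum()), 1)
    loss = 1.0 - float(dice[counted].sum()) / k
    if not with_grad:
        return loss
    grad = np.zeros_like(probs, dtype=np.float64)
    shp = (1, ncls) + (1,) * (probs.ndim - 2)
    w = counted.astype(np.float64).reshape(shp)
    numb = num.reshape(shp)
    denb = den.reshape(shp)
    # d dice_c / d p_c(x) = (2 t - dice_c) / den ; loss = 1 - mean
    grad = -(w / k) * (2.0 * t - (numb / denb)) / denb
    return loss, grad


def cross_entropy(logits, target, *, with_grad=False):
    """Mean per-pixel categorical cross-entropy from logits."""
    _check_shapes(logits, target)
    p = softmax(logits.astype(np.float64))
    t = one_hot(target, logits.shape[1])
    npix = target.size
    loss = float(-(t * np.log(np.clip(p, 1e-12, None))).sum()) / npix
    if not with_grad:
        return loss
    return loss, (p - t) / npix


def combined_loss(logits, target, w_dice, w_ce, *, eps=1e-5,
                  include_empty=False, with_grad=False):
    """``w_dice * L_dice + w_ce * L_ce`` evaluated on logits.

    Returns ``(loss, parts)`` or ``(loss, grad_wrt_logits, parts)`` where
    ``parts = (dice_component, ce_component)``.
    """
    if w_dice < 0 or w_ce < 0:
        raise ValueError("loss weights must be non-negative")
    p = softmax(logits.astype(np.float64))
    if not with_grad:
        ld = dice_loss(p, target, eps=eps, include_empty=include_empty)
        lc = cross_entropy(logits, target)
        return w_dice * ld + w_ce * lc, (ld, lc)
    ld, gd_p = dice_loss(p, target, eps=eps, include_empty=include_empty,
                         with_grad=True)
    lc, gc_z = cross_entropy(logits, target, with_grad=True)
    # chain dice grad through the softmax Jacobian
    gd_z = p * (gd_p - (gd_p * p).sum(axis=1, keepdims=True))
    grad = w_dice * gd_z + w_ce * gc_z
    return w_dice * ld + w_ce * lc, grad.astype(logits.dtype), (ld, lc)


class CombinedLoss:
    """Stateful wrapper bound to a weight pair (picked by model dim)."""

    def __init__(self, w_dice=None, w_ce=None, *, dim=2, eps=1e-5,
                 include_empty=False):
        if w_dice is None or w_ce is None:
            w_dice, w_ce = default_loss_weights(dim)
        if w_dice < 0 or w_ce < 0:
            raise ValueError("loss weights must be non-negative")
        self.w_dice, self.w_ce = float(w_dice), float(w_ce)
        self.eps = eps
        self.include_empty = include_empty

    def __call__(self, logits, target):
        return combined_loss(logits, target, self.w_dice, self.w_ce,
                             eps=self.eps, include_empty=self.include_empty,
                             with_grad=True)
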