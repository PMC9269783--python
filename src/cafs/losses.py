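"""Softmax cross-entropy over per-pixel class logits.

The objective used for teacher pretraining, student pseudo-mask training and
the feedback comparison is the same: the mean over batch and pixels of
``-sum_c t_c log softmax(z)_c``, where the target ``t`` is either a hard
binary mask (one-hot over the two classes) or a soft class distribution.
"""

from __future__ import annotations

import numpy as np

from .errors import ShapeError

__all__ = ["cross_entropy", "log_softmax"]


def log_softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=axis, keepdims=True))


def _soft_target(target: np.ndarray, n_classes: int) -> np.ndarray:
    """Hard (B, H, W) integer masks -> one-hot (B, C, H, W); soft passes through."""
    if target.ndim == 4:
        return target
    if target.ndim != 3:
        raise ShapeError(f"target must be (B, H, W) or (B, C, H, W), "
                         f"got {target.shape}")
    t = np.zeros((target.shape[0], n_classes) + target.shape[1:],
                 dtype=np.float64)
    for c in range(n_classes):
        t[:, c] = target == c
    return t


def cross_entropy(pred_logits: np.ndarray, target: np.ndarray,
                  with_grad: bool = False):
    """Mean cross-entropy; optionally also d(loss)/d(logits).

    pred_logits: (B, C, H, W) finite logits.
    target: hard integer masks (B, H, W) or soft distributions (B, C, H, W).
    Returns ``loss`` or ``(loss, dlogits)``.
    """
    if not np.all(np.isfinite(pred_logits)):
        raise FloatingPointError("non-finite logits passed to cross_entropy")
    t = _soft_target(target, pred_logits.shape[1])
    if t.shape != pred_logits.shape:
        raise ShapeError(f"target shape {t.shape} does not match logits "
                         f"{pred_logits.shape}")
    logp = log_softmax(pred_logits, axis=1)
    n = pred_logits.shape[0] * pred_logits.shape[2] * pred_logits.shape[3]
    loss = float(-(t * logp).sum() / n)
    if not with_grad:
        return loss
    p = np.exp(logp)
    dlogits = (p - t) / n
    return loss, dlogits.astype(pred_logits.dtype)
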