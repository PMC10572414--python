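"""Hybrid segmentation loss: equally weighted cross-entropy and Dice loss.

The training criterion is ``L = ½·L_CE + ½·L_Dice``.  Cross-entropy is the
mean over pixels of ``−Σ_classes p·log q`` (ground-truth one-hot ``p``,
predicted probability ``q``).  The Dice loss is computed on the foreground
(cavity) channel, ``1 − (2·Σ y·ŷ + α)/(Σ y + Σ ŷ + α)``; the smoothing
constant α keeps the loss defined when an image contains no cavity at all
(``y = ŷ = 0`` gives a loss of exactly 0).

Two entry points: :func:`hybrid_loss` evaluates the loss on numpy
probability maps and returns its components; :func:`hybrid_loss_graph`
builds the same quantity inside the autograd graph from raw logits, for
training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = ["LossValue", "hybrid_loss", "hybrid_loss_graph", "DEFAULT_ALPHA"]

DEFAULT_ALPHA = 1.0
_CLIP = 1e-7


@dataclass(frozen=True)
class LossValue:
    total: float
    ce: float
    dice: float


def _validate(pred_probs: np.ndarray, target_onehot: np.ndarray):
    if pred_probs.shape != target_onehot.shape:
        raise ValueError(f"shape mismatch: {pred_probs.shape} vs {target_onehot.shape}")
    if pred_probs.ndim != 3 or pred_probs.shape[0] != 2:
        raise ValueError("expected class-first maps of shape (2, H, W)")
    sums = pred_probs.sum(axis=0)
    if np.abs(sums - 1.0).max() > 1e-4:
        raise ValueError("prediction probabilities must sum to 1 per pixel")
    tsums = target_onehot.sum(axis=0)
    if not np.allclose(tsums, 1.0) or not np.isin(target_onehot, (0, 1)).all():
        raise ValueError("target must be one-hot")


def hybrid_loss(pred_probs: np.ndarray, target_onehot: np.ndarray,
                alpha: float = DEFAULT_ALPHA) -> LossValue:
    """Evaluate the hybrid loss on a (2, H, W) probability map."""
    pred_probs = np.asarray(pred_probs, dtype=np.float64)
    target_onehot = np.asarray(target_onehot, dtype=np.float64)
    _validate(pred_probs, target_onehot)

    n = pred_probs.shape[1] * pred_probs.shape[2]
    q = np.clip(pred_probs, _CLIP, 1.0 - _CLIP)
    ce = float(-(target_onehot * np.log(q)).sum() / n)

    y = target_onehot[1]
    yhat = pred_probs[1]
    inter = float((y * yhat).sum())
    dice_loss = 1.0 - (2.0 * inter + alpha) / (float(y.sum() + yhat.sum()) + alpha)

    return LossValue(total=0.5 * ce + 0.5 * dice_loss, ce=ce, dice=dice_loss)


def hybrid_loss_graph(logits: Tensor, target_onehot: np.ndarray,
                      alpha: float = DEFAULT_ALPHA) -> Tensor:
    """Hybrid loss as an autograd node, from (N, 2, H, W) logits.

    The Dice term pools foreground sums over the whole batch, so a batch of
    one reproduces :func:`hybrid_loss` on normalized probabilities.
    """
    target = np.asarray(target_onehot, dtype=np.float64)
    if logits.shape != target.shape:
        raise ValueError(f"shape mismatch: {logits.shape} vs {target.shape}")
    n_pix = logits.shape[0] * logits.shape[2] * logits.shape[3]

    logq = logits.log_softmax(axis=1)
    ce = -(Tensor(target) * logq).sum() * (1.0 / n_pix)

    probs = logq.exp()
    y = target[:, 1]
    yhat = probs[:, 1]
    inter = (Tensor(y) * yhat).sum()
    denom = yhat.sum() + (float(y.sum()) + alpha)
    dice_loss = 1.0 - (inter * 2.0 + alpha) / denom

    return ce * 0.5 + dice_loss * 0.5
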