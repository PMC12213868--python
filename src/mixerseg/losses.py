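"""Combined binary cross-entropy + Dice loss for imbalanced lesion masks.

Lesions occupy a small fraction of an ultrasound frame, so plain pixelwise
cross-entropy is dominated by the background. The training loss therefore
adds a smoothed soft-Dice term that scores only the overlap between the
predicted probability mass and the foreground:

``L = mean_BCE(y, p) + 1 - (2 * sum(y * p) + eps) / (sum(y) + sum(p) + eps)``

with the mean taken over all pixels of all samples in the batch, the sums
pooled over the batch, and ``eps = 1e-6`` so an empty target with an empty
prediction contributes zero Dice loss.
"""

from __future__ import annotations

import numpy as np

DICE_EPS = 1e-6
CLIP_EPS = 1e-7


def _validate(y_true: np.ndarray, y_pred: np.ndarray) -> None:
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch: labels {y_true.shape} vs predictions {y_pred.shape}")
    if np.any(y_pred < 0.0) or np.any(y_pred > 1.0):
        raise ValueError("predicted probabilities must lie in [0, 1] before clipping")


def bce_loss(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean binary cross-entropy over all pixels, probabilities clipped to [eps, 1-eps]."""
    _validate(y_true, y_pred)
    p = np.clip(y_pred.astype(np.float64), CLIP_EPS, 1.0 - CLIP_EPS)
    y = y_true.astype(np.float64)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def dice_loss(y_true: np.ndarray, y_pred: np.ndarray, eps: float = DICE_EPS) -> float:
    """Smoothed soft-Dice loss pooled over all pixels."""
    _validate(y_true, y_pred)
    y = y_true.astype(np.float64)
    p = y_pred.astype(np.float64)
    inter = float((y * p).sum())
    return float(1.0 - (2.0 * inter + eps) / (y.sum() + p.sum() + eps))


def combined_loss(y_true: np.ndarray, y_pred: np.ndarray, eps: float = DICE_EPS) -> float:
    """Sum of mean BCE and smoothed Dice loss (non-negative scalar)."""
    return bce_loss(y_true, y_pred) + dice_loss(y_true, y_pred, eps)


def combined_loss_grad(y_true: np.ndarray, y_pred: np.ndarray, eps: float = DICE_EPS) -> np.ndarray:
    """Gradient of :func:`combined_loss` with respect to the predicted probabilities.

    Probabilities are clipped as in the loss; the clip is treated as the
    identity in the gradient.
    """
    _validate(y_true, y_pred)
    y = y_true.astype(np.float64)
    p = np.clip(y_pred.astype(np.float64), CLIP_EPS, 1.0 - CLIP_EPS)
    n = p.size
    dbce = (p - y) / (p * (1.0 - p)) / n
    s = y.sum() + p.sum() + eps
    inter2 = 2.0 * (y * p).sum() + eps
    ddice = (inter2 / (s * s)) - (2.0 * y / s)
    return (dbce + ddice).astype(y_pred.dtype, copy=False)
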