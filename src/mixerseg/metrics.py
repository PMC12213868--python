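"""Segmentation evaluation metrics.

Overlap scores (Jaccard index, Dice similarity coefficient) compare a binary
ground-truth mask ``P`` with a binary predicted mask ``Q``; pixel-count
metrics (accuracy, precision, recall) derive from the TP/TN/FP/FN confusion
tallies; ROC-AUC ranks per-pixel probabilities against the binary labels.

Conventions (documented, configurable where noted):

* Jaccard and Dice of two empty masks are 1.0 by default (a correctly
  predicted lesion-free image is a perfect match).
* Precision/recall with a zero denominator return 1.0 when the numerator is
  also zero, else 0.0.
* Report rows follow the column order Jaccard, DSC, recall, accuracy,
  precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

METRIC_COLUMNS = ("jaccard", "dsc", "recall", "accuracy", "precision")


def _check_binary(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return arr.astype(np.float64)


def jaccard(p_true: np.ndarray, q_pred: np.ndarray, empty_value: float = 1.0) -> float:
    """Intersection over union of two binary masks."""
    p = _check_binary(p_true, "ground-truth mask")
    q = _check_binary(q_pred, "predicted mask")
    if p.shape != q.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {q.shape}")
    inter = float((p * q).sum())
    union = float(p.sum() + q.sum() - inter)
    if union == 0.0:
        return empty_value
    return inter / union


def dsc(p_true: np.ndarray, q_pred: np.ndarray, empty_value: float = 1.0) -> float:
    """Dice similarity coefficient ``2|P & Q| / (|P| + |Q|)``.

    Related to the Jaccard index by ``DSC = 2J / (1 + J)`` for every binary
    pair.
    """
    p = _check_binary(p_true, "ground-truth mask")
    q = _check_binary(q_pred, "predicted mask")
    if p.shape != q.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {q.shape}")
    denom = float(p.sum() + q.sum())
    if denom == 0.0:
        return empty_value
    return 2.0 * float((p * q).sum()) / denom


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies; all non-negative, summing to the total pixel count."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(p_true: np.ndarray, q_pred: np.ndarray) -> ConfusionCounts:
    """TP/TN/FP/FN pixel tallies of a binary mask pair."""
    p = _check_binary(p_true, "ground-truth mask").astype(bool)
    q = _check_binary(q_pred, "predicted mask").astype(bool)
    if p.shape != q.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {q.shape}")
    return ConfusionCounts(
        tp=int(np.sum(p & q)),
        tn=int(np.sum(~p & ~q)),
        fp=int(np.sum(~p & q)),
        fn=int(np.sum(p & ~q)),
    )


def _safe_ratio(num: int, denom: int) -> float:
    if denom == 0:
        return 1.0 if num == 0 else 0.0
    return num / denom


def accuracy_precision_recall(cc: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, precision, recall) from confusion counts."""
    acc = _safe_ratio(cc.tp + cc.tn, cc.total)
    prec = _safe_ratio(cc.tp, cc.tp + cc.fp)
    rec = _safe_ratio(cc.tp, cc.tp + cc.fn)
    return acc, prec, rec


def auc_roc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Pixelwise ROC-AUC; ties count one half (rank statistic).

    Raises ``ValueError`` when only one class is present, where the AUC is
    undefined.
    """
    y = np.asarray(y_true).ravel()
    s = np.asarray(scores).ravel()
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    if y.min() == y.max():
        raise ValueError("AUC undefined: labels contain a single class")
    return float(roc_auc_score(y, s))


def evaluate_pair(p_true: np.ndarray, q_pred: np.ndarray) -> dict:
    """All thresholded metrics of one mask pair, in report column order."""
    cc = confusion_counts(p_true, q_pred)
    acc, prec, rec = accuracy_precision_recall(cc)
    return {
        "jaccard": jaccard(p_true, q_pred),
        "dsc": dsc(p_true, q_pred),
        "recall": rec,
        "accuracy": acc,
        "precision": prec,
    }


def metric_report(p_true: np.ndarray, q_pred: np.ndarray, ids=None):
    """Per-image metric rows plus a mean summary row as a DataFrame.

    Parameters
    ----------
    p_true, q_pred
        Stacked binary masks of shape ``(n, h, w)`` (or ``(n, h, w, 1)``).
    ids
        Optional row labels; defaults to the image index.
    """
    import pandas as pd

    p = np.asarray(p_true).reshape(len(p_true), -1)
    q = np.asarray(q_pred).reshape(len(q_pred), -1)
    rows = [evaluate_pair(pi, qi) for pi, qi in zip(p, q)]
    frame = pd.DataFrame(rows, columns=list(METRIC_COLUMNS))
    frame.insert(0, "image", list(ids) if ids is not None else list(range(len(rows))))
    summary = frame[list(METRIC_COLUMNS)].mean()
    summary_row = pd.DataFrame([["mean", *summary.tolist()]], columns=frame.columns)
    return pd.concat([frame, summary_row], ignore_index=True)
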