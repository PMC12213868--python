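"""Training loop (Adam on the combined BCE + Dice loss) and evaluation."""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .config import TrainConfig
from .data import AugmentParams, ImageMaskPair, apply_transform, sample_transform
from .losses import combined_loss, combined_loss_grad, dice_loss
from .metrics import METRIC_COLUMNS, auc_roc, metric_report
from .model import SegmentationModel, predict_masks
from .nn import Adam, BatchNorm2d


def update_batchnorm_stats(
    model: SegmentationModel, images: np.ndarray, batch_size: Optional[int] = None
) -> None:
    """Re-estimate BatchNorm running statistics by streaming ``images``.

    Short runs leave the exponential running moments (momentum 0.99) far
    from the activation statistics the trained weights produce, which would
    corrupt inference-mode forward passes. This pass replaces them with the
    arithmetic mean of the batch statistics over the given data, after which
    training- and inference-mode outputs agree on that data.
    """
    bns = [layer for layer in model.iter_layers() if isinstance(layer, BatchNorm2d)]
    saved = [bn.momentum for bn in bns]
    n = len(images)
    step = batch_size or n
    for i, start in enumerate(range(0, n, step)):
        for bn in bns:
            bn.momentum = i / (i + 1.0)  # incremental arithmetic mean
        model.forward(images[start : start + step], training=True)
    for bn, momentum in zip(bns, saved):
        bn.momentum = momentum


def _batch_metrics(masks: np.ndarray, probs: np.ndarray) -> tuple[float, float]:
    """(pixel accuracy, soft-free Dice of the thresholded prediction)."""
    pred = probs > 0.5
    truth = masks > 0.5
    acc = float(np.mean(pred == truth))
    inter = float(np.sum(pred & truth))
    denom = float(pred.sum() + truth.sum())
    dice = 1.0 if denom == 0 else 2.0 * inter / denom
    return acc, dice


def fit(
    model: SegmentationModel,
    images: np.ndarray,
    masks: np.ndarray,
    train_cfg: Optional[TrainConfig] = None,
    val_images: Optional[np.ndarray] = None,
    val_masks: Optional[np.ndarray] = None,
    stop_dice: Optional[float] = None,
    max_steps: Optional[int] = None,
    augment: Optional[AugmentParams] = None,
    log=None,
) -> pd.DataFrame:
    """Train ``model`` in place; returns the per-epoch history.

    Parameters
    ----------
    images, masks
        NHWC training tensors; masks binary in {0, 1}.
    stop_dice
        Optional early exit once the running epoch Dice (thresholded at 0.5)
        reaches this value.
    max_steps
        Optional hard cap on optimisation steps across epochs.
    augment
        Optional augmentation bounds; when given, every training example is
        passed through one freshly sampled joint transform per epoch
        (online augmentation).

    Raises
    ------
    RuntimeError
        If the loss becomes non-finite (reports learning rate and step).
    """
    cfg = train_cfg or TrainConfig()
    opt = Adam(model.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.shuffle_seed)
    n = len(images)
    step = 0
    rows = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses, accs, dices = [], [], []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = images[idx], masks[idx]
            if augment is not None:
                xa, ya = [], []
                for img, msk in zip(xb, yb):
                    t = sample_transform(augment, rng, size=img.shape[0])
                    pair = apply_transform(
                        ImageMaskPair(image=img[..., 0], mask=(msk[..., 0] > 0.5).astype(np.uint8)), t
                    )
                    xa.append(pair.image)
                    ya.append(pair.mask)
                xb = np.stack(xa)[..., None].astype(images.dtype)
                yb = np.stack(ya)[..., None].astype(masks.dtype)
            probs = model.forward(xb, training=True)
            loss = combined_loss(yb, probs)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at step {step} (lr={cfg.learning_rate}); aborting"
                )
            opt.zero_grad()
            model.backward(combined_loss_grad(yb, probs))
            opt.step()
            acc, dice = _batch_metrics(yb, probs)
            losses.append(loss)
            accs.append(acc)
            dices.append(dice)
            step += 1
            if max_steps is not None and step >= max_steps:
                break
        row = {
            "epoch": epoch,
            "step": step,
            "train_loss": float(np.mean(losses)),
            "train_accuracy": float(np.mean(accs)),
            "train_dice": float(np.mean(dices)),
        }
        if val_images is not None and val_masks is not None and len(val_images):
            vp = model.forward(val_images, training=False)
            row["val_loss"] = combined_loss(val_masks, vp)
            vacc, vdice = _batch_metrics(val_masks, vp)
            row["val_accuracy"] = vacc
            row["val_dice"] = vdice
        rows.append(row)
        if log is not None:
            log(row)
        if stop_dice is not None and row["train_dice"] >= stop_dice:
            break
        if max_steps is not None and step >= max_steps:
            break
    update_batchnorm_stats(model, images)
    return pd.DataFrame(rows)


def evaluate_model(
    model: SegmentationModel,
    images: np.ndarray,
    masks: np.ndarray,
    threshold: float = 0.5,
) -> dict:
    """Per-image metric table, mean summary and pooled pixelwise ROC-AUC.

    Returns a dict with ``per_image`` (DataFrame: one row per image plus a
    mean row, columns in the order Jaccard, DSC, recall, accuracy,
    precision), ``mean`` (dict of the mean row) and ``auc`` (pooled over all
    pixels of the set; ``None`` when the pooled labels are single-class).
    """
    probs = model.forward(images, training=False)
    pred = predict_masks(model, images, threshold=threshold)
    truth = (masks > 0.5).astype(np.uint8)
    report = metric_report(truth[..., 0], pred[..., 0])
    mean_row = report[report["image"] == "mean"].iloc[0]
    y = truth.ravel()
    try:
        auc = auc_roc(y, probs.ravel())
    except ValueError:
        auc = None
    return {
        "per_image": report,
        "mean": {k: float(mean_row[k]) for k in METRIC_COLUMNS},
        "auc": auc,
    }


def overfit_batch(
    model: SegmentationModel,
    images: np.ndarray,
    masks: np.ndarray,
    max_steps: int = 300,
    lr: float = 1e-3,
    target_dice: float = 0.95,
) -> tuple[float, int]:
    """Fit a fixed batch until the thresholded Dice reaches ``target_dice``.

    Returns ``(best_dice, steps_used)``. A network whose residual paths and
    normalisation are wired correctly memorises a four-image batch well
    within a few hundred Adam steps.
    """
    opt = Adam(model.params(), lr=lr)
    best = 0.0
    for step in range(1, max_steps + 1):
        probs = model.forward(images, training=True)
        _, dice = _batch_metrics(masks, probs)
        best = max(best, dice)
        if dice >= target_dice:
            update_batchnorm_stats(model, images)
            return dice, step
        opt.zero_grad()
        model.backward(combined_loss_grad(masks, probs))
        opt.step()
    probs = model.forward(images, training=True)
    _, dice = _batch_metrics(masks, probs)
    update_batchnorm_stats(model, images)
    return max(best, dice), max_steps
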