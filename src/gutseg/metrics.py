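"""Dice and IoU overlap scores and the BCE + soft-dice training loss.

Scores are computed per class channel over the spatial pixels, averaged
over channels, then over the batch. A small smoothing epsilon makes the
empty-vs-empty case score 1.0, so all-background slices do not drag down
epoch means. Reported (as opposed to trained-on) scores binarize soft
predictions at a configurable threshold.

Closed forms on hard masks: dice = 2|A∩B| / (|A|+|B|), iou = |A∩B| / |A∪B|,
related by dice = 2·iou / (1 + iou).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class MetricShapeError(ValueError):
    """Prediction and truth shapes disagree."""


class PredictionDomainError(ValueError):
    """Soft predictions fall outside [0, 1]."""


@dataclass(frozen=True)
class MetricConfig:
    """Smoothing and binarization settings shared across the pipeline."""

    smoothing_epsilon: float = 1e-6
    binarization_threshold: float = 0.5

    def __post_init__(self):
        if self.smoothing_epsilon <= 0:
            raise ValueError("smoothing_epsilon must be > 0")
        if not 0.0 < self.binarization_threshold < 1.0:
            raise ValueError("binarization_threshold must be in (0, 1)")


def _as_batch(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalize both arrays to (N, pixels, C); accepts (H,W), (H,W,C), (N,H,W,C)."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise MetricShapeError(f"pred shape {pred.shape} != truth shape {truth.shape}")
    if pred.ndim == 2:
        pred, truth = pred[None, :, :, None], truth[None, :, :, None]
    elif pred.ndim == 3:
        pred, truth = pred[None], truth[None]
    elif pred.ndim != 4:
        raise MetricShapeError(f"expected 2-4 dims, got shape {pred.shape}")
    n, h, w, c = pred.shape
    return pred.reshape(n, h * w, c), truth.reshape(n, h * w, c)


def _maybe_binarize(pred: np.ndarray, threshold: float | None) -> np.ndarray:
    return (pred > threshold).astype(np.float64) if threshold is not None else pred


def dice(
    pred: np.ndarray,
    truth: np.ndarray,
    epsilon: float = 1e-6,
    threshold: float | None = None,
) -> float:
    """Dice coefficient (2|A∩B|+ε) / (|A|+|B|+ε), channel- then batch-mean.

    ``threshold`` binarizes a soft prediction first; leave ``None`` for the
    soft (differentiable) form used inside the loss.
    """
    p, t = _as_batch(pred, truth)
    p = _maybe_binarize(p, threshold)
    inter = (p * t).sum(axis=1)
    sizes = p.sum(axis=1) + t.sum(axis=1)
    per_channel = (2.0 * inter + epsilon) / (sizes + epsilon)
    return float(per_channel.mean(axis=1).mean())


def iou(
    pred: np.ndarray,
    truth: np.ndarray,
    epsilon: float = 1e-6,
    threshold: float | None = None,
) -> float:
    """IoU (Jaccard) coefficient (|A∩B|+ε) / (|A∪B|+ε), same aggregation."""
    p, t = _as_batch(pred, truth)
    p = _maybe_binarize(p, threshold)
    inter = (p * t).sum(axis=1)
    union = p.sum(axis=1) + t.sum(axis=1) - inter
    per_channel = (inter + epsilon) / (union + epsilon)
    return float(per_channel.mean(axis=1).mean())


_CLIP = 1e-7  # probability clip for the log terms


def training_loss(pred: np.ndarray, truth: np.ndarray, epsilon: float = 1e-6) -> float:
    """Binary cross-entropy plus (1 − soft dice), both channel-averaged.

    Zero (to within the smoothing/clipping tolerance) iff ``pred`` equals
    ``truth`` exactly.
    """
    loss, _ = training_loss_and_grad(pred, truth, epsilon)
    return loss


def training_loss_and_grad(
    pred: np.ndarray, truth: np.ndarray, epsilon: float = 1e-6
) -> tuple[float, np.ndarray]:
    """Loss value and its gradient with respect to the soft prediction.

    The gradient has the shape of ``pred`` and feeds the network's backward
    pass (the final sigmoid layer folds in its own derivative).
    """
    pred_arr = np.asarray(pred, dtype=np.float64)
    if pred_arr.min(initial=0.0) < 0.0 or pred_arr.max(initial=0.0) > 1.0:
        raise PredictionDomainError("soft predictions must lie in [0, 1]")
    p, t = _as_batch(pred_arr, truth)
    n, _, c = p.shape

    pc = np.clip(p, _CLIP, 1.0 - _CLIP)
    bce = float(-(t * np.log(pc) + (1.0 - t) * np.log(1.0 - pc)).mean())
    dbce = (pc - t) / (pc * (1.0 - pc)) / p.size

    inter = (p * t).sum(axis=1, keepdims=True)
    denom = p.sum(axis=1, keepdims=True) + t.sum(axis=1, keepdims=True) + epsilon
    soft_dice = (2.0 * inter + epsilon) / denom
    dice_loss = float(1.0 - soft_dice.mean())
    # d/dp of (2I+ε)/D  =  (2t·D − (2I+ε)) / D²; channel/batch mean scales by 1/(n·c)
    ddice = -(2.0 * t * denom - (2.0 * inter + epsilon)) / denom**2 / (n * c)

    grad = (dbce + ddice).reshape(np.asarray(pred).shape)
    return bce + dice_loss, grad
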