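"""Evaluation metrics: mask IoU and AP, trait regression errors, SPP classes.

Detection quality uses COCO-style mask average precision (greedy
confidence-descending one-to-one matching, 101-point interpolated PR
curve) at a fixed IoU threshold. Trait accuracy uses MAE, RMSE and R^2.
Seed counts are additionally discretized into 1-4 classes (counts above 4
clipped into class 4) to form a confusion matrix with overall accuracy
and adjacent-class accuracy (Acc@+/-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "mask_iou",
    "DetectionMatch",
    "match_detections",
    "average_precision",
    "regression_metrics",
    "SppConfusion",
    "spp_confusion",
]

N_CLASSES = 4


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """|a ∩ b| / |a ∪ b| for two same-size binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a canvas")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        raise ValueError("IoU undefined for two empty masks")
    return float(np.count_nonzero(a & b)) / union


@dataclass
class DetectionMatch:
    """Predictions matched to ground truths at one IoU threshold."""

    threshold: float
    confidences: np.ndarray  # descending
    is_tp: np.ndarray        # per prediction, in confidence order
    n_gt: int


def match_detections(
    predictions: list[tuple[np.ndarray, float]],
    ground_truths: list[np.ndarray],
    threshold: float,
) -> DetectionMatch:
    """Greedy one-to-one matching in descending confidence.

    Each prediction claims the unmatched ground truth with the highest
    IoU, provided that IoU >= threshold; otherwise it is a false positive.
    """
    if not ground_truths:
        raise ValueError("at least one ground truth is required")
    order = sorted(range(len(predictions)), key=lambda i: -predictions[i][1])
    matched = [False] * len(ground_truths)
    is_tp = np.zeros(len(predictions), dtype=bool)
    confs = np.zeros(len(predictions))
    for rank, i in enumerate(order):
        mask, conf = predictions[i]
        confs[rank] = conf
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(ground_truths):
            if matched[j]:
                continue
            try:
                iou = mask_iou(mask, gt)
            except ValueError:
                iou = 0.0
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0 and best_iou >= threshold:
            matched[best_j] = True
            is_tp[rank] = True
    return DetectionMatch(
        threshold=threshold, confidences=confs, is_tp=is_tp, n_gt=len(ground_truths)
    )


def average_precision(match: DetectionMatch) -> float:
    """Area under the interpolated PR curve (COCO 101-point rule)."""
    if match.n_gt < 1:
        raise ValueError("no ground truths")
    if match.is_tp.size == 0:
        return 0.0
    tp = np.cumsum(match.is_tp)
    fp = np.cumsum(~match.is_tp)
    recall = tp / match.n_gt
    precision = tp / (tp + fp)
    # precision envelope: max precision at any recall >= R
    recall_points = np.linspace(0.0, 1.0, 101)
    interp = np.zeros_like(recall_points)
    for k, rp in enumerate(recall_points):
        sel = recall >= rp - 1e-12
        interp[k] = precision[sel].max() if sel.any() else 0.0
    return float(interp.mean())


def regression_metrics(pred, gt) -> tuple[float, float, float]:
    """(MAE, RMSE, R^2) of predictions against ground truth."""
    pred = np.asarray(pred, dtype=float)
    gt = np.asarray(gt, dtype=float)
    if pred.shape != gt.shape:
        raise ValueError("pred and gt must have equal length")
    if pred.size < 2:
        raise ValueError("need at least two samples")
    err = pred - gt
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    ss_tot = float(np.sum((gt - gt.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined for constant ground truth")
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot
    return mae, rmse, r2


@dataclass
class SppConfusion:
    confusion: np.ndarray   # rows = true class, cols = predicted class (1..4)
    overall_acc: float
    acc_within_1: float
    n: int


def spp_confusion(pred_counts, gt_counts) -> SppConfusion:
    """Seed-count confusion over the 1-4 classes (counts > 4 clip into 4)."""
    pred = np.asarray(pred_counts, dtype=int)
    gt = np.asarray(gt_counts, dtype=int)
    if pred.size == 0 or pred.shape != gt.shape:
        raise ValueError("pred and gt counts must be nonempty and of equal length")
    pc = np.clip(pred, 1, N_CLASSES)
    gc = np.clip(gt, 1, N_CLASSES)
    confusion = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    for p, g in zip(pc, gc):
        confusion[g - 1, p - 1] += 1
    overall = float(np.trace(confusion)) / pred.size
    within_1 = float(np.count_nonzero(np.abs(pred - gt) <= 1)) / pred.size
    return SppConfusion(
        confusion=confusion, overall_acc=overall, acc_within_1=within_1, n=int(pred.size)
    )
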