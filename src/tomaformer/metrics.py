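"""Segmentation and detection metrics.

Segmentation quality is scored with a per-class confusion matrix, IoU and
Dice (averaged over the three tomato classes, background excluded), and
a pixelwise one-vs-rest ROC AUC. Detection quality uses a mask-derived
mAP: each 8-connected component of a class in the predicted mask yields a
minimum bounding rectangle (the least/highest occupied row and column)
scored by the component's mean predicted class probability; boxes are
then greedily matched to ground-truth boxes at an IoU threshold and AP is
the area under the all-point-interpolated precision-recall curve.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from sklearn.metrics import roc_auc_score

from .scenes import N_CLASSES

TOMATO_CLASSES = (1, 2, 3)

_STRUCT_8 = np.ones((3, 3), dtype=int)
_STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclasses.dataclass
class InstanceBox:
    """Axis-aligned box (inclusive pixel bounds) with a confidence score."""

    class_label: int
    row_min: int
    col_min: int
    row_max: int
    col_max: int
    score: float = 1.0
    image_id: int = 0

    def __post_init__(self):
        if self.row_min > self.row_max or self.col_min > self.col_max:
            raise ValueError("degenerate box bounds")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")

    @property
    def area(self) -> int:
        return (self.row_max - self.row_min + 1) * (self.col_max - self.col_min + 1)


@dataclasses.dataclass
class MetricReport:
    classwise_iou: dict
    mean_iou: float
    mean_dice: float
    map_score: float | None
    auc: float | None
    confusion: np.ndarray

    def to_dict(self) -> dict:
        return {
            "classwise_iou": {int(k): (None if v is None or np.isnan(v) else float(v))
                              for k, v in self.classwise_iou.items()},
            "mean_iou": float(self.mean_iou),
            "mean_dice": float(self.mean_dice),
            "map_score": None if self.map_score is None else float(self.map_score),
            "auc": None if self.auc is None else float(self.auc),
            "confusion": self.confusion.tolist(),
        }


def confusion_matrix(pred: np.ndarray, truth: np.ndarray,
                     c_se: int = N_CLASSES) -> np.ndarray:
    """Entry (a, b) counts pixels with truth label a and predicted label b."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    for name, m in (("pred", pred), ("truth", truth)):
        if m.min() < 0 or m.max() >= c_se:
            raise ValueError(f"{name} labels outside [0, {c_se})")
    counts = np.bincount(truth.ravel() * c_se + pred.ravel(),
                         minlength=c_se * c_se)
    return counts.reshape(c_se, c_se)


def iou_and_dice(confusion: np.ndarray, include_background: bool = False):
    """Per-class IoU plus means of IoU and Dice over the tomato classes.

    Classes absent from both prediction and truth are excluded from the
    means (their per-class entry is NaN).
    """
    tp = np.diag(confusion).astype(float)
    fp = confusion.sum(axis=0) - tp
    fn = confusion.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = tp / (tp + fp + fn)
        dice = 2 * tp / (2 * tp + fp + fn)
    classes = range(confusion.shape[0]) if include_background else TOMATO_CLASSES
    classwise = {c: iou[c] for c in classes}
    present = [c for c in classes if tp[c] + fp[c] + fn[c] > 0]
    mean_iou = float(np.mean([iou[c] for c in present])) if present else float("nan")
    mean_dice = float(np.mean([dice[c] for c in present])) if present else float("nan")
    return classwise, mean_iou, mean_dice


def masks_to_instances(mask: np.ndarray, probs: np.ndarray | None = None,
                       connectivity: int = 8, image_id: int = 0) -> list[InstanceBox]:
    """Extract one box per connected component of each tomato class.

    ``probs`` is an optional R x C x c_se probability map; the box score is
    the mean of the component's own class probability (1.0 without probs).
    """
    if probs is not None and probs.shape[:2] != mask.shape:
        raise ValueError("probability map does not match mask shape")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = _STRUCT_8 if connectivity == 8 else _STRUCT_4
    boxes: list[InstanceBox] = []
    for cls in TOMATO_CLASSES:
        binary = mask == cls
        if not binary.any():
            continue
        labels, n = ndimage.label(binary, structure=structure)
        for comp in range(1, n + 1):
            rows, cols = np.nonzero(labels == comp)
            score = 1.0 if probs is None else float(probs[rows, cols, cls].mean())
            boxes.append(InstanceBox(cls, int(rows.min()), int(cols.min()),
                                     int(rows.max()), int(cols.max()),
                                     score=score, image_id=image_id))
    return boxes


def box_iou(a: InstanceBox, b: InstanceBox) -> float:
    """IoU of two boxes with inclusive pixel bounds."""
    ri = max(a.row_min, b.row_min), min(a.row_max, b.row_max)
    ci = max(a.col_min, b.col_min), min(a.col_max, b.col_max)
    if ri[0] > ri[1] or ci[0] > ci[1]:
        return 0.0
    inter = (ri[1] - ri[0] + 1) * (ci[1] - ci[0] + 1)
    return inter / (a.area + b.area - inter)


def _class_ap(preds: list[InstanceBox], truths: list[InstanceBox],
              iou_threshold: float) -> float:
    """All-point-interpolated AP for one class; matching is per image."""
    n_gt = len(truths)
    order = sorted(range(len(preds)), key=lambda i: -preds[i].score)
    matched: set[int] = set()
    tp = np.zeros(len(preds))
    for rank, i in enumerate(order):
        p = preds[i]
        best_iou, best_j = 0.0, None
        for j, g in enumerate(truths):
            if j in matched or g.image_id != p.image_id:
                continue
            iou = box_iou(p, g)
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j is not None and best_iou >= iou_threshold:
            matched.add(best_j)
            tp[rank] = 1.0
    cum_tp = np.cumsum(tp)
    recall = cum_tp / n_gt
    precision = cum_tp / np.arange(1, len(preds) + 1)
    # precision envelope, then area under the stepwise PR curve
    ap, prev_r = 0.0, 0.0
    for r in np.unique(recall[tp > 0]):
        p_at = precision[recall >= r].max()
        ap += (r - prev_r) * p_at
        prev_r = r
    return ap


def average_precision(pred_boxes: list[InstanceBox], truth_boxes: list[InstanceBox],
                      iou_threshold: float = 0.5):
    """Per-class AP and their mean over tomato classes.

    Classes with neither ground truth nor predictions are excluded; a
    class with ground truth but no predictions scores 0; matching never
    crosses image ids.
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError("iou_threshold must lie in (0, 1)")
    per_class: dict[int, float] = {}
    for cls in TOMATO_CLASSES:
        preds = [b for b in pred_boxes if b.class_label == cls]
        truths = [b for b in truth_boxes if b.class_label == cls]
        if not truths:
            continue  # no ground truth: class not scoreable
        if not preds:
            per_class[cls] = 0.0
            continue
        per_class[cls] = _class_ap(preds, truths, iou_threshold)
    if not per_class:
        return {}, None
    return per_class, float(np.mean(list(per_class.values())))


def pixel_auc(probs: np.ndarray, truth: np.ndarray) -> float | None:
    """Macro one-vs-rest ROC AUC over tomato classes present in truth.

    ``probs`` is R x C x c_se (or flattened N x c_se); classes absent from
    the truth, or covering every pixel, are excluded. Returns None when no
    class is scoreable.
    """
    flat_p = probs.reshape(-1, probs.shape[-1])
    flat_t = truth.ravel()
    if flat_p.shape[0] != flat_t.shape[0]:
        raise ValueError("probability map does not match truth shape")
    aucs = []
    for cls in TOMATO_CLASSES:
        y = flat_t == cls
        if y.all() or not y.any():
            continue
        aucs.append(roc_auc_score(y, flat_p[:, cls]))
    return float(np.mean(aucs)) if aucs else None
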