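"""Quantitative protocols: PR sweep, ROC area, moving-object extraction.

A normalized saliency map (values in [0, 255]) is binarized at every
integer threshold tau in 0..255 with the strict rule ``foreground =
saliency > tau``, so tau = 255 predicts nothing and tau = 0 predicts every
non-zero pixel.  Precision is defined as 1 when nothing is predicted and
recall as 1 when the ground truth is empty (the usual conventions for
degenerate sweeps).  The ROC area integrates TPR over FPR across the same
sweep by the trapezoid rule, with the predict-everything endpoint (1, 1)
appended so a perfect map scores exactly 1 and an uninformative constant
map scores 0.5.

Moving-object extraction binarizes a map at a single threshold, cleans the
mask by morphological opening then closing with a disk, and reports
8-connected component bounding boxes.  A ground-truth box counts as
detected when at least 30% of its pixels are foreground; recall is the
detected fraction of ground-truth boxes and precision the fraction of
predicted boxes overlapping a detected one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label, regionprops
from skimage.morphology import closing, disk, opening

__all__ = [
    "EvalCurves",
    "DetectionResult",
    "pr_curve",
    "roc_area",
    "extract_moving_objects",
    "detection_metrics",
]

Box = tuple[int, int, int, int]

#: fraction of a ground-truth box that must be foreground to count as a hit
HIT_FRACTION = 0.30


@dataclass
class EvalCurves:
    """Threshold-indexed PR/ROC arrays from a 0..255 sweep."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    roc_area: float

    def to_csv(self, path) -> None:
        rows = np.column_stack(
            [self.thresholds, self.precision, self.recall, self.tpr, self.fpr]
        )
        np.savetxt(
            path,
            rows,
            delimiter=",",
            header="threshold,precision,recall,tpr,fpr",
            comments="",
            fmt=["%d", "%.6f", "%.6f", "%.6f", "%.6f"],
        )


@dataclass
class DetectionResult:
    """Outcome of moving-object extraction on one frame."""

    mask: np.ndarray
    boxes: list[Box]


def _check_pair(saliency: np.ndarray, gt_mask: np.ndarray):
    s = np.asarray(saliency, dtype=float)
    g = np.asarray(gt_mask)
    if s.shape != g.shape:
        raise ValueError(f"shape mismatch: saliency {s.shape} vs mask {g.shape}")
    return s, g.astype(bool)


def pr_curve(saliency: np.ndarray, gt_mask: np.ndarray) -> EvalCurves:
    """Precision/recall and TPR/FPR over thresholds 0..255.

    ``saliency`` should be normalized to [0, 255]; ``gt_mask`` is binary.
    """
    s, g = _check_pair(saliency, gt_mask)
    n_pos = int(g.sum())
    n_neg = g.size - n_pos
    thresholds = np.arange(256)
    # count pixels strictly above each tau from the sorted values
    pos_sorted = np.sort(s[g])
    neg_sorted = np.sort(s[~g])
    tp = n_pos - np.searchsorted(pos_sorted, thresholds, side="right")
    fp = n_neg - np.searchsorted(neg_sorted, thresholds, side="right")
    predicted = tp + fp
    precision = np.where(predicted > 0, tp / np.maximum(predicted, 1), 1.0)
    recall = np.where(n_pos > 0, tp / max(n_pos, 1), 1.0)
    fpr = fp / max(n_neg, 1) if n_neg > 0 else np.zeros_like(fp, dtype=float)
    curves = EvalCurves(
        thresholds=thresholds,
        precision=precision.astype(float),
        recall=recall.astype(float),
        tpr=recall.astype(float),
        fpr=fpr.astype(float),
        roc_area=0.0,
    )
    curves.roc_area = _area(curves.fpr, curves.tpr)
    return curves


def _area(fpr: np.ndarray, tpr: np.ndarray) -> float:
    # sweep points plus the predict-everything endpoint, sorted by fpr
    xs = np.concatenate([fpr, [1.0]])
    ys = np.concatenate([tpr, [1.0]])
    order = np.lexsort((ys, xs))
    return float(np.trapezoid(ys[order], xs[order]))


def roc_area(saliency: np.ndarray, gt_mask: np.ndarray) -> float:
    """Area under the ROC curve of the 256-threshold sweep, in [0, 1]."""
    return pr_curve(saliency, gt_mask).roc_area


def extract_moving_objects(
    saliency: np.ndarray,
    threshold: int = 128,
    morph_radius: int = 2,
) -> DetectionResult:
    """Binarize a normalized map and extract connected-component boxes.

    Opening removes specks smaller than the structuring disk; closing fills
    holes of the same size.  Components are 8-connected.
    """
    s = np.asarray(saliency, dtype=float)
    mask = s > threshold
    if morph_radius > 0:
        selem = disk(morph_radius)
        mask = closing(opening(mask, selem), selem).astype(bool)
    labeled = label(mask, connectivity=2)
    boxes: list[Box] = []
    for region in regionprops(labeled):
        y0, x0, y1, x1 = region.bbox
        boxes.append((x0, y0, x1 - x0, y1 - y0))
    return DetectionResult(mask=mask, boxes=boxes)


def _check_box(box: Box, shape: tuple[int, int]) -> Box:
    x, y, w, h = box
    if w <= 0 or h <= 0 or x < 0 or y < 0 or x + w > shape[1] or y + h > shape[0]:
        raise ValueError(f"malformed or out-of-bounds box {box} for grid {shape}")
    return box


def _overlaps(a: Box, b: Box) -> bool:
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    return ax < bx + bw and bx < ax + aw and ay < by + bh and by < ay + ah


def detection_metrics(
    result: DetectionResult, gt_boxes: list[Box]
) -> tuple[float, float]:
    """(recall, precision) of an extraction against ground-truth boxes.

    A ground-truth box is detected iff at least 30% of its pixels are
    foreground in ``result.mask``; a predicted box is a true positive iff
    it overlaps any detected ground-truth box.
    """
    mask = result.mask
    detected: list[Box] = []
    for box in gt_boxes:
        x, y, w, h = _check_box(box, mask.shape)
        frac = mask[y:y + h, x:x + w].mean()
        if frac >= HIT_FRACTION:
            detected.append(box)
    recall = len(detected) / len(gt_boxes) if gt_boxes else 1.0
    if not result.boxes:
        return recall, 1.0
    tp = sum(1 for pb in result.boxes if any(_overlaps(pb, g) for g in detected))
    return recall, tp / len(result.boxes)
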