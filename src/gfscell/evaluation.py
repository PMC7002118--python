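"""COCO-style detection evaluation: IoU, AP50 / AP75 / AP(0.5:0.95).

Average precision follows the COCO protocol: detections are matched
greedily in score order to the unmatched ground truth of the same class and
image with the highest IoU at or above the threshold; precision-recall
points are reduced to the 101-point interpolated AP (precision envelope
sampled at recalls 0, 0.01, …, 1.00); per-threshold AP is averaged over the
classes that have ground truth, and AP(0.5:0.95) averages the ten
thresholds 0.50, 0.55, …, 0.95.  All APs are reported on a 0-100 scale.

Boxes are real rectangles [x_min, y_min, x_max, y_max] with area
(x_max − x_min)·(y_max − y_min); no +1 pixel convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

IOU_THRESHOLDS = np.round(np.arange(0.50, 0.96, 0.05), 2)


@dataclass(frozen=True)
class GtBox:
    image_id: int
    label: str
    box: tuple[float, float, float, float]


@dataclass(frozen=True)
class DetBox:
    image_id: int
    label: str
    box: tuple[float, float, float, float]
    score: float


@dataclass(frozen=True)
class EvalResult:
    ap_50: float
    ap_75: float
    ap_avg: float
    per_threshold: tuple[float, ...]
    per_class: dict

    def summary(self) -> str:
        return (
            f"AP(0.5:0.95) = {self.ap_avg:.2f}   AP50 = {self.ap_50:.2f}   "
            f"AP75 = {self.ap_75:.2f}"
        )


def iou(box_a, box_b) -> float:
    """Intersection-over-union of two well-ordered boxes; 0 when disjoint
    or when both boxes have zero area."""
    ax0, ay0, ax1, ay1 = box_a
    bx0, by0, bx1, by1 = box_b
    if ax1 < ax0 or ay1 < ay0 or bx1 < bx0 or by1 < by0:
        raise InvalidInputError("boxes must satisfy min <= max per axis")
    iw = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    ih = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union if union > 0 else 0.0


def match_detections(
    dets: list[DetBox], gts: list[GtBox], iou_threshold: float
) -> list[bool]:
    """Greedy one-to-one TP/FP assignment for one class.

    ``dets`` must be sorted by score descending (ties keep input order);
    each detection matches the unmatched ground truth of its image with the
    highest IoU ≥ threshold.
    """
    gt_by_image: dict[int, list[int]] = {}
    for i, g in enumerate(gts):
        gt_by_image.setdefault(g.image_id, []).append(i)
    matched = [False] * len(gts)
    flags = []
    for d in dets:
        best_iou, best_j = iou_threshold, -1
        for j in gt_by_image.get(d.image_id, ()):
            if matched[j]:
                continue
            v = iou(d.box, gts[j].box)
            if v >= best_iou and (best_j == -1 or v > best_iou):
                best_iou, best_j = v, j
        if best_j >= 0:
            matched[best_j] = True
            flags.append(True)
        else:
            flags.append(False)
    return flags


def average_precision(flags: list[bool], n_gt: int) -> float | None:
    """101-point interpolated AP on a 0-100 scale.

    ``flags`` are per-detection TP/FP indicators in score order.  Returns
    None (undefined) when there is neither ground truth nor detections.
    """
    if n_gt < 0:
        raise InvalidInputError("n_gt must be >= 0")
    if n_gt == 0:
        return None if len(flags) == 0 else 0.0
    if len(flags) == 0:
        return 0.0

    tp = np.cumsum(np.asarray(flags, dtype=float))
    fp = np.cumsum(1.0 - np.asarray(flags, dtype=float))
    recall = tp / n_gt
    precision = tp / (tp + fp)
    # precision envelope: best precision at any recall >= r
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    sample_recalls = np.linspace(0.0, 1.0, 101)
    idx = np.searchsorted(recall, sample_recalls, side="left")
    sampled = np.where(idx < len(envelope), envelope[np.minimum(idx, len(envelope) - 1)], 0.0)
    return float(sampled.mean() * 100.0)


def _sorted_dets(dets: list[DetBox]) -> list[DetBox]:
    return sorted(dets, key=lambda d: -d.score)  # stable: ties keep input order


def evaluate(dets: list[DetBox], gts: list[GtBox]) -> EvalResult:
    """Per-class, per-threshold AP summary over a detection/ground-truth set.

    Classes present in the detections but absent from the ground truth are
    warned about and contribute only false positives (they are excluded from
    the class average, matching the convention of evaluating only annotated
    categories).
    """
    gt_classes = sorted({g.label for g in gts})
    det_classes = {d.label for d in dets}
    for c in det_classes - set(gt_classes):
        logger.warning("detections contain unknown class %r (no ground truth); FP-only", c)

    per_class: dict[str, list[float]] = {}
    per_threshold = []
    for thr in IOU_THRESHOLDS:
        class_aps = []
        for c in gt_classes:
            c_gts = [g for g in gts if g.label == c]
            c_dets = _sorted_dets([d for d in dets if d.label == c])
            flags = match_detections(c_dets, c_gts, float(thr))
            ap = average_precision(flags, len(c_gts))
            if ap is not None:
                class_aps.append(ap)
                per_class.setdefault(c, []).append(ap)
        per_threshold.append(float(np.mean(class_aps)) if class_aps else 0.0)

    per_threshold = tuple(per_threshold)
    ap50 = per_threshold[0]
    ap75 = per_threshold[5]
    return EvalResult(
        ap_50=ap50,
        ap_75=ap75,
        ap_avg=float(np.mean(per_threshold)),
        per_threshold=per_threshold,
        per_class={c: tuple(v) for c, v in per_class.items()},
    )
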