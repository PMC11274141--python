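"""Detection and classification evaluation.

Confusion-matrix metrics (precision, recall/sensitivity, specificity, all
reported as percentages) plus PR-curve mean average precision with IoU-based
greedy matching of detections to ground-truth boxes — the de-facto
object-detection evaluation convention: detections are visited in order of
descending confidence and each claims the unmatched truth of highest IoU at
or above the threshold.

A zero denominator raises :class:`UndefinedMetricError` rather than
reporting a silent zero: "no positives predicted" is not the same finding
as "precision 0%".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, UndefinedMetricError
from .segmentation import BoundingBox

__all__ = [
    "ConfusionCounts",
    "Detection",
    "PRCurve",
    "iou",
    "match_detections",
    "precision",
    "recall",
    "specificity",
    "classification_metrics",
    "average_precision",
    "mean_average_precision",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Tp / Fp / Fn / Tn.  Tn is only meaningful for classification; a
    detector has no natural negative and carries Tn = 0."""

    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ParameterError(f"confusion counts must be non-negative: {self}")


@dataclass(frozen=True)
class Detection:
    box: BoundingBox
    confidence: float
    class_id: int = 0

    def __post_init__(self):
        if not 0.0 <= self.confidence <= 1.0:
            raise ParameterError(f"confidence must lie in [0, 1], got {self.confidence}")


@dataclass(frozen=True)
class PRCurve:
    """Precision-recall points in sweep order (recall non-decreasing)."""

    recall: np.ndarray
    precision: np.ndarray
    interpolation: str = "all_point"

    def __post_init__(self):
        r = np.asarray(self.recall, dtype=float)
        p = np.asarray(self.precision, dtype=float)
        if r.shape != p.shape:
            raise ParameterError("recall and precision must have equal length")
        if np.any(np.diff(r) < 0):
            raise ParameterError("recall must be non-decreasing along the curve")
        object.__setattr__(self, "recall", r)
        object.__setattr__(self, "precision", p)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two half-open boxes, in [0, 1]."""
    ix = max(0, min(a.x1, b.x1) - max(a.x0, b.x0))
    iy = max(0, min(a.y1, b.y1) - max(a.y0, b.y0))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def match_detections(dets: list[Detection], truths: list[BoundingBox],
                     iou_threshold: float = 0.5,
                     ) -> tuple[ConfusionCounts, list[bool]]:
    """Greedy confidence-ordered matching.

    Returns the confusion counts (Tn = 0: detection has no negatives) and a
    per-detection flag, in the *input* order, saying whether that detection
    matched a truth.
    """
    if not 0.0 < iou_threshold <= 1.0:
        raise ParameterError(f"iou_threshold must lie in (0, 1], got {iou_threshold}")
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    taken = [False] * len(truths)
    matched = [False] * len(dets)
    for i in order:
        best_j, best_iou = -1, iou_threshold
        for j, t in enumerate(truths):
            if taken[j]:
                continue
            v = iou(dets[i].box, t)
            if v >= best_iou and (best_j < 0 or v > best_iou):
                best_j, best_iou = j, v
        if best_j >= 0:
            taken[best_j] = True
            matched[i] = True
    tp = sum(matched)
    return ConfusionCounts(tp=tp, fp=len(dets) - tp, fn=len(truths) - tp), matched


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        raise UndefinedMetricError(f"{name} is undefined: denominator is zero")
    return 100.0 * num / den


def precision(c: ConfusionCounts) -> float:
    """Tp / (Tp + Fp), as a percentage."""
    return _ratio(c.tp, c.tp + c.fp, "precision")


def recall(c: ConfusionCounts) -> float:
    """Tp / (Tp + Fn) (sensitivity), as a percentage."""
    return _ratio(c.tp, c.tp + c.fn, "recall")


def specificity(c: ConfusionCounts) -> float:
    """Tn / (Fp + Tn), as a percentage."""
    return _ratio(c.tn, c.fp + c.tn, "specificity")


def classification_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(precision, recall/sensitivity, specificity) in percent."""
    return precision(c), recall(c), specificity(c)


def _pr_points(dets: list[Detection], truths: list[BoundingBox],
               iou_threshold: float) -> PRCurve:
    """Sweep the confidence ranking to accumulate the raw PR points."""
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    _, matched = match_detections(dets, truths, iou_threshold)
    tp = fp = 0
    rs, ps = [], []
    for i in order:
        if matched[i]:
            tp += 1
        else:
            fp += 1
        rs.append(tp / len(truths))
        ps.append(tp / (tp + fp))
    return PRCurve(np.array(rs), np.array(ps))


def average_precision(dets: list[Detection], truths: list[BoundingBox],
                      iou_threshold: float = 0.5, mode: str = "all_point") -> float:
    """Area under the interpolated PR curve for one class.

    ``all_point``: precision is replaced by its running maximum to the right
    (the precision envelope) and integrated over every recall increment.
    ``eleven_point``: mean of the interpolated precision at recalls
    0.0, 0.1, ..., 1.0.
    """
    if mode not in ("all_point", "eleven_point"):
        raise ParameterError(f"mode must be 'all_point' or 'eleven_point', got {mode!r}")
    if not truths:
        raise ParameterError("average precision needs at least one ground-truth box")
    if not dets:
        return 0.0
    curve = _pr_points(dets, truths, iou_threshold)
    r = np.concatenate(([0.0], curve.recall))
    p = np.concatenate(([0.0], curve.precision))
    envelope = np.maximum.accumulate(p[::-1])[::-1]
    if mode == "eleven_point":
        levels = np.linspace(0.0, 1.0, 11)
        interp = [envelope[r >= lv].max() if np.any(r >= lv) else 0.0 for lv in levels]
        return float(np.mean(interp))
    return float(np.sum(np.diff(r) * envelope[1:]))


def mean_average_precision(per_class_dets: dict[int, list[Detection]],
                           per_class_truths: dict[int, list[BoundingBox]],
                           iou_threshold: float = 0.5, mode: str = "all_point") -> float:
    """Mean of per-class AP over every class that has ground truth.

    Classes with zero truths are excluded with a warning (their AP is
    undefined); at least one class must have truth.
    """
    aps = []
    for cls in sorted(per_class_truths):
        truths = per_class_truths[cls]
        if not truths:
            warnings.warn(f"class {cls} has no ground-truth boxes; excluded from mAP", stacklevel=2)
            continue
        aps.append(average_precision(per_class_dets.get(cls, []), truths, iou_threshold, mode))
    if not aps:
        raise ParameterError("mAP needs at least one class with ground truth")
    return float(np.mean(aps))
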