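"""Bounding-box detection evaluation: IoU, matching, 11-point AP.

Implements the standard single-class object-detection arithmetic used to
score the machine-vision models of an injection robot: intersection-
over-union between axis-aligned boxes, greedy confidence-ordered
matching of predictions to ground truth at a fixed IoU threshold, and
PASCAL-VOC-style 11-point interpolated average precision.

Conventions (fixed for determinism):

* a prediction matches only the single best-IoU *unmatched* ground-truth
  box on its image, and only if that IoU is >= the threshold;
* predictions are processed in descending confidence, ties broken by
  input order; identical-IoU ground-truth candidates by lowest index;
* precision = TP / (TP + FP), recall = TP / (TP + FN), both cumulative
  in confidence rank;
* AP = (1/11) * sum over r in {0.0, 0.1, ..., 1.0} of the maximum
  precision attained at any rank with recall >= r (0 if unreachable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Box",
    "MatchResult",
    "iou",
    "match_detections",
    "average_precision_11pt",
    "evaluate_detections",
    "load_boxes_csv",
    "write_boxes_csv",
]


@dataclass(frozen=True)
class Box:
    """Axis-aligned bounding box, top-left origin, y growing downward."""

    image_id: str
    x: float
    y: float
    width: float
    height: float
    confidence: Optional[float] = None
    class_label: str = "object"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(
                f"degenerate box on image {self.image_id!r}: "
                f"width={self.width}, height={self.height}"
            )
        if self.confidence is not None and not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def area(self) -> float:
        return self.width * self.height


def iou(a: Box, b: Box) -> float:
    """Intersection area over union area of two boxes on the same image."""
    if a.image_id != b.image_id:
        raise ValueError(
            f"boxes on different images: {a.image_id!r} vs {b.image_id!r}"
        )
    ix = min(a.x + a.width, b.x + b.width) - max(a.x, b.x)
    iy = min(a.y + a.height, b.y + b.height) - max(a.y, b.y)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    # clamp: rounding of (x+w)-x can push the ratio marginally above 1
    return min(1.0, inter / (a.area + b.area - inter))


@dataclass
class MatchResult:
    """Outcome of matching predictions to ground truth at one threshold.

    ``is_tp`` is ordered by descending prediction confidence; cumulative
    TP/FP curves follow that order.
    """

    n_ground_truth: int
    is_tp: List[bool] = field(default_factory=list)
    confidences: List[float] = field(default_factory=list)

    @property
    def tp_cumulative(self) -> np.ndarray:
        return np.cumsum(np.asarray(self.is_tp, dtype=int))

    @property
    def fp_cumulative(self) -> np.ndarray:
        return np.cumsum(~np.asarray(self.is_tp, dtype=bool))

    @property
    def n_true_positive(self) -> int:
        return int(sum(self.is_tp))

    @property
    def n_false_negative(self) -> int:
        return self.n_ground_truth - self.n_true_positive


def match_detections(
    predictions: Sequence[Box],
    ground_truths: Sequence[Box],
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedily match predictions to ground-truth boxes.

    Predictions are visited in descending confidence.  Each claims the
    unmatched ground-truth box on its own image with the highest IoU; it
    is a true positive iff that IoU is >= ``iou_threshold``, in which
    case the ground-truth box is consumed.  Everything else is a false
    positive; leftover ground truth counts as false negatives.
    """
    order = sorted(
        range(len(predictions)),
        key=lambda i: -(predictions[i].confidence if predictions[i].confidence is not None else 1.0),
    )
    matched = [False] * len(ground_truths)
    result = MatchResult(n_ground_truth=len(ground_truths))
    for i in order:
        pred = predictions[i]
        best_iou = 0.0
        best_j = -1
        for j, gt in enumerate(ground_truths):
            if matched[j] or gt.image_id != pred.image_id:
                continue
            v = iou(pred, gt)
            if v > best_iou:  # strict: ties keep the lowest-index candidate
                best_iou = v
                best_j = j
        hit = best_j >= 0 and best_iou >= iou_threshold
        if hit:
            matched[best_j] = True
        result.is_tp.append(hit)
        result.confidences.append(
            pred.confidence if pred.confidence is not None else 1.0
        )
    return result


def average_precision_11pt(match: MatchResult) -> float:
    """11-point interpolated average precision of a match result.

    At each recall level r in {0.0, 0.1, ..., 1.0} the interpolated
    precision is the maximum precision over all confidence cutoffs whose
    recall is >= r (0 when no cutoff reaches r); AP is their mean.
    """
    if match.n_ground_truth == 0:
        raise ValueError("average precision undefined with zero ground-truth boxes")
    tp = match.tp_cumulative
    if tp.size == 0:
        return 0.0
    fp = match.fp_cumulative
    precision = tp / (tp + fp)
    recall = tp / match.n_ground_truth
    levels = np.arange(11) / 10.0  # correctly-rounded k/10, exact vs recall ratios
    interp = np.empty(11)
    for k, r in enumerate(levels):
        reachable = precision[recall >= r - 1e-12]
        interp[k] = reachable.max() if reachable.size else 0.0
    return float(interp.mean())


def evaluate_detections(
    predictions: Sequence[Box],
    ground_truths: Sequence[Box],
    iou_threshold: float = 0.5,
) -> dict:
    """Per-class AP, precision and recall at a fixed IoU threshold."""
    classes = sorted({b.class_label for b in ground_truths})
    out = {}
    for cls in classes:
        preds = [b for b in predictions if b.class_label == cls]
        gts = [b for b in ground_truths if b.class_label == cls]
        m = match_detections(preds, gts, iou_threshold)
        tp, fp, fn = m.n_true_positive, len(preds) - m.n_true_positive, m.n_false_negative
        out[cls] = {
            "ap": average_precision_11pt(m),
            "n_ground_truth": len(gts),
            "n_predictions": len(preds),
            "tp": tp,
            "fp": fp,
            "fn": fn,
            "precision": tp / (tp + fp) if preds else float("nan"),
            "recall": tp / (tp + fn),
        }
    return out


def load_boxes_csv(path: str | Path, predictions: bool = False) -> List[Box]:
    """Read a box table (image_id, x, y, width, height[, confidence, class_label])."""
    df = pd.read_csv(path)
    required = {"image_id", "x", "y", "width", "height"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if predictions and "confidence" not in df.columns:
        raise ValueError(f"{path}: prediction file requires a confidence column")
    boxes = []
    for row in df.itertuples(index=False):
        boxes.append(
            Box(
                image_id=str(row.image_id),
                x=float(row.x),
                y=float(row.y),
                width=float(row.width),
                height=float(row.height),
                confidence=float(row.confidence) if predictions else None,
                class_label=str(getattr(row, "class_label", "object")),
            )
        )
    return boxes


def write_boxes_csv(boxes: Sequence[Box], path: str | Path) -> None:
    rows = []
    for b in boxes:
        row = {
            "image_id": b.image_id,
            "x": b.x,
            "y": b.y,
            "width": b.width,
            "height": b.height,
            "class_label": b.class_label,
        }
        if b.confidence is not None:
            row["confidence"] = b.confidence
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
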