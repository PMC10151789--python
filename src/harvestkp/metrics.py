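"""Evaluation: matching confusion counts, precision/recall, IoU and AP.

Matching evaluation counts per ground-truth pair: a predicted (fruit, stem)
pair is a true positive iff the same identity appears in the truth for the
same scene.  Average precision follows the COCO protocol — greedy
score-descending matching at each IoU threshold in {0.50, 0.55, ..., 0.95}
and all-point interpolation of the precision–recall curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .exceptions import ValidationError
from .matching import MatchPair
from .scene_io import InstanceMask

#: the 10 IoU thresholds 0.50:0.05:0.95 of the COCO mAP protocol
COCO_IOU_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass
class PRResult:
    """Precision and recall; an undefined ratio (zero denominator) is stored
    as None, never silently as 0."""

    precision: Optional[float]
    recall: Optional[float]

    def __post_init__(self) -> None:
        for v in (self.precision, self.recall):
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValidationError(f"precision/recall {v} outside [0, 1]")


def precision_recall(counts: ConfusionCounts) -> PRResult:
    """precision = TP/(TP+FP), recall = TP/(TP+FN)."""
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp > 0 else None
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn > 0 else None
    return PRResult(precision, recall)


def mask_iou(a, b) -> float:
    """Intersection over union of two binary masks on the same canvas."""
    ra = a.raster if isinstance(a, InstanceMask) else np.asarray(a, bool)
    rb = b.raster if isinstance(b, InstanceMask) else np.asarray(b, bool)
    if ra.shape != rb.shape:
        raise ValidationError(f"canvas mismatch {ra.shape} vs {rb.shape}")
    union = np.count_nonzero(ra | rb)
    if union == 0:
        raise ValidationError("IoU of two empty masks is undefined")
    return np.count_nonzero(ra & rb) / union


def match_confusion(predicted_pairs: Sequence[Sequence[MatchPair]],
                    truth_pairs: Sequence[Sequence[MatchPair]]) -> ConfusionCounts:
    """Confusion counts for matching over parallel per-scene pair lists.

    tp: predicted pairs whose (fruit_index, stem_index) identity appears in
    the same scene's truth; fp: predicted pairs without a truth counterpart;
    fn: truth pairs never predicted.
    """
    if len(predicted_pairs) != len(truth_pairs):
        raise ValidationError(
            f"{len(predicted_pairs)} predicted scenes vs {len(truth_pairs)} truth scenes"
        )
    tp = fp = fn = 0
    for pred, truth in zip(predicted_pairs, truth_pairs):
        pred_ids = {p.identity for p in pred}
        truth_ids = {t.identity for t in truth}
        tp += len(pred_ids & truth_ids)
        fp += len(pred_ids - truth_ids)
        fn += len(truth_ids - pred_ids)
    return ConfusionCounts(tp, fp, fn)


def _greedy_match_flags(ious: np.ndarray, order: np.ndarray, threshold: float) -> np.ndarray:
    """COCO greedy assignment: predictions in score order take the unclaimed
    truth of highest IoU >= threshold.  Returns per-prediction TP flags in
    score order."""
    n_pred, n_truth = ious.shape
    taken = np.zeros(n_truth, dtype=bool)
    flags = np.zeros(n_pred, dtype=bool)
    for rank, p in enumerate(order):
        best_j = -1
        best_iou = threshold
        for j in range(n_truth):
            if taken[j]:
                continue
            if ious[p, j] >= best_iou:
                best_iou = ious[p, j]
                best_j = j
        if best_j >= 0:
            taken[best_j] = True
            flags[rank] = True
    return flags


def average_precision(predictions: Sequence[InstanceMask],
                      truths: Sequence[InstanceMask],
                      iou_thresholds: Optional[Sequence[float]] = None) -> float:
    """AP of scored mask predictions against ground truth, averaged over the
    IoU thresholds (default the 10 COCO thresholds 0.50–0.95).

    Predictions are ranked by descending score (ties keep input order); the
    precision–recall curve is integrated with all-point interpolation.
    """
    if not truths:
        raise ValidationError("average_precision requires at least one truth instance")
    if iou_thresholds is None:
        iou_thresholds = COCO_IOU_THRESHOLDS
    if not predictions:
        return 0.0
    scores = np.array([p.score if p.score is not None else 0.0 for p in predictions])
    order = np.argsort(-scores, kind="stable")
    ious = np.array([[mask_iou(p, t) for t in truths] for p in predictions])

    aps = []
    for thr in iou_thresholds:
        flags = _greedy_match_flags(ious, order, thr)
        tp_cum = np.cumsum(flags)
        fp_cum = np.cumsum(~flags)
        prec = tp_cum / (tp_cum + fp_cum)
        rec = tp_cum / len(truths)
        aps.append(_all_point_ap(prec, rec))
    return float(np.mean(aps))


def _all_point_ap(precision: np.ndarray, recall: np.ndarray) -> float:
    mrec = np.concatenate(([0.0], recall, [1.0]))
    mpre = np.concatenate(([0.0], precision, [0.0]))
    for i in range(mpre.size - 2, -1, -1):  # precision envelope
        mpre[i] = max(mpre[i], mpre[i + 1])
    idx = np.flatnonzero(mrec[1:] != mrec[:-1]) + 1
    return float(np.sum((mrec[idx] - mrec[idx - 1]) * mpre[idx]))


def evaluation_report(counts: ConfusionCounts, ap: Optional[float] = None) -> dict:
    """JSON-ready evaluation summary; percentages at one decimal place."""
    pr = precision_recall(counts)
    report = {
        "tp": counts.tp,
        "fp": counts.fp,
        "fn": counts.fn,
        "precision": pr.precision,
        "recall": pr.recall,
        "precision_pct": None if pr.precision is None else round(100 * pr.precision, 1),
        "recall_pct": None if pr.recall is None else round(100 * pr.recall, 1),
    }
    if ap is not None:
        report["average_precision"] = ap
    return report


def format_report(report: dict) -> str:
    lines = [
        f"TP {report['tp']}  FP {report['fp']}  FN {report['fn']}",
        f"precision: {_fmt_pct(report['precision_pct'])}",
        f"recall:    {_fmt_pct(report['recall_pct'])}",
    ]
    if "average_precision" in report:
        lines.append(f"AP[.50:.95]: {report['average_precision']:.3f}")
    return "\n".join(lines)


def _fmt_pct(value) -> str:
    return "undefined" if value is None else f"{value:.1f}%"
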