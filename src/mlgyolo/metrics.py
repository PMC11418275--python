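"""Detection and localization evaluation statistics.

Precision = 100*TP/(TP+FP), Recall = 100*TP/(TP+FN) (0 when the denominator
is 0). AP sweeps score-ranked predictions, greedily matching each to at most
one unmatched ground-truth box at the IoU threshold, and sums precision over
recall increments; for a single class mAP equals AP. Localization errors per
axis are the mean absolute error and the standard error s/sqrt(n) with the
sample standard deviation s.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boxes import iou_matrix

__all__ = ["precision", "recall", "average_precision", "match_predictions",
           "DetectionMetrics", "evaluate_detections",
           "LocalizationErrorReport", "localization_errors"]


def precision(tp: int, fp: int) -> float:
    """100*TP/(TP+FP); 0 when no predictions were kept."""
    if tp < 0 or fp < 0:
        raise ValueError("counts must be non-negative")
    return 100.0 * tp / (tp + fp) if tp + fp else 0.0


def recall(tp: int, fn: int) -> float:
    """100*TP/(TP+FN); 0 when there are no positives."""
    if tp < 0 or fn < 0:
        raise ValueError("counts must be non-negative")
    return 100.0 * tp / (tp + fn) if tp + fn else 0.0


def _rank(scores: np.ndarray, areas: np.ndarray) -> np.ndarray:
    """Deterministic ranking: score desc, then area desc, then index."""
    idx = np.arange(len(scores))
    return np.lexsort((idx, -areas, -scores))


def match_predictions(predictions, ground_truth, iou_threshold: float = 0.5):
    """Greedy score-ordered matching.

    predictions: sequence of (image_id, xyxy, score);
    ground_truth: mapping image_id -> (m,4) xyxy array.
    Returns (hits bool array in rank order, n_gt).
    """
    n_gt = int(sum(len(np.atleast_2d(g)) if np.size(g) else 0
                   for g in ground_truth.values()))
    if n_gt == 0:
        raise ValueError("average precision is undefined without ground truth")
    if len(predictions) == 0:
        return np.zeros(0, dtype=bool), n_gt
    img_ids = [p[0] for p in predictions]
    boxes = np.array([np.asarray(p[1], dtype=np.float64) for p in predictions])
    scores = np.array([p[2] for p in predictions], dtype=np.float64)
    areas = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])
    order = _rank(scores, areas)
    used = {k: np.zeros(len(np.atleast_2d(v)), dtype=bool)
            for k, v in ground_truth.items() if np.size(v)}
    hits = np.zeros(len(order), dtype=bool)
    for rank, i in enumerate(order):
        key = img_ids[i]
        if key not in used:
            continue
        gt = np.atleast_2d(ground_truth[key])
        ious = iou_matrix(boxes[i], gt)[0]
        ious[used[key]] = -1.0
        j = int(np.argmax(ious))
        if ious[j] >= iou_threshold:
            used[key][j] = True
            hits[rank] = True
    return hits, n_gt


def average_precision(predictions, ground_truth, iou_threshold: float = 0.5,
                      interpolated: bool = True) -> float:
    """AP (%) for a single class.

    ``interpolated=True`` uses the all-point interpolation (precision
    envelope); ``False`` sums the raw precision staircase over recall
    increments.
    """
    hits, n_gt = match_predictions(predictions, ground_truth, iou_threshold)
    if hits.size == 0:
        return 0.0
    tp = np.cumsum(hits)
    fp = np.cumsum(~hits)
    rec = tp / n_gt
    prec = tp / (tp + fp)
    if interpolated:
        mrec = np.concatenate(([0.0], rec, [1.0]))
        mpre = np.concatenate(([1.0], prec, [0.0]))
        mpre = np.maximum.accumulate(mpre[::-1])[::-1]
        ap = float(np.sum(np.diff(mrec) * mpre[1:]))
    else:
        drec = np.diff(np.concatenate(([0.0], rec)))
        ap = float(np.sum(prec * drec))
    return 100.0 * ap


@dataclass
class DetectionMetrics:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    map50: float
    pr_points: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        assert 0.0 <= self.precision <= 100.0
        assert 0.0 <= self.recall <= 100.0
        assert 0.0 <= self.map50 <= 100.0


def evaluate_detections(predictions, ground_truth, iou_threshold: float = 0.5,
                        conf_threshold: float = 0.25) -> DetectionMetrics:
    """AP over all predictions plus point precision/recall above a confidence."""
    ap = average_precision(predictions, ground_truth, iou_threshold)
    kept = [p for p in predictions if p[2] >= conf_threshold]
    n_gt = int(sum(len(np.atleast_2d(g)) if np.size(g) else 0
                   for g in ground_truth.values()))
    if kept:
        hits, _ = match_predictions(kept, ground_truth, iou_threshold)
        tp = int(hits.sum())
        fp = int(len(kept) - tp)
    else:
        tp, fp = 0, 0
    fn = n_gt - tp
    hits_all, _ = match_predictions(predictions, ground_truth, iou_threshold) \
        if predictions else (np.zeros(0, bool), n_gt)
    tp_c = np.cumsum(hits_all)
    fp_c = np.cumsum(~hits_all)
    pr = list(zip((tp_c / n_gt).tolist(), (tp_c / np.maximum(tp_c + fp_c, 1)).tolist()))
    return DetectionMetrics(tp, fp, fn, precision(tp, fp), recall(tp, fn), ap, pr)


@dataclass
class LocalizationErrorReport:
    """Per-axis positioning-error summary in the robot base frame (mm)."""
    n: int
    mean_abs: tuple[float, float, float]     # mean |error| per axis
    standard_error: tuple[float, float, float]  # s/sqrt(n) per axis

    def __post_init__(self):
        assert all(v >= 0 for v in self.mean_abs)
        assert all(v >= 0 for v in self.standard_error)


def localization_errors(errors) -> LocalizationErrorReport:
    """Summarise signed per-axis errors (n,3) -> mean |e| and s/sqrt(n)."""
    e = np.atleast_2d(np.asarray(errors, dtype=np.float64))
    if e.ndim != 2 or e.shape[1] != 3:
        raise ValueError("errors must be an (n, 3) array of X/Y/Z errors")
    n = e.shape[0]
    if n < 2:
        raise ValueError("standard error needs at least 2 measurement points")
    mean_abs = tuple(float(v) for v in np.abs(e).mean(axis=0))
    se = tuple(float(v) for v in e.std(axis=0, ddof=1) / np.sqrt(n))
    return LocalizationErrorReport(n, mean_abs, se)
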