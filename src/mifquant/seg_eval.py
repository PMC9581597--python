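"""Instance-segmentation evaluation: IoU matching and detection metrics.

Given a ground-truth and a predicted label mask, every candidate
(ground-truth, prediction) pair with nonzero pixel overlap is scored by
intersection-over-union,

    IoU = |I_P ∩ I_GT| / |I_P ∪ I_GT|,

and pairs exceeding a threshold ``T`` become detections.  The resulting
TP/FP/FN counts feed four normalised metrics::

    precision          = TP / (TP + FP)
    recall             = TP / (TP + FN)
    average_precision  = TP / (TP + FN + FP)
    f1                 = 2 * precision * recall / (precision + recall)

``average_precision`` here is the detection-level summary combining all
three counts (sometimes called the aggregated Jaccard / AP@T in the nuclei
segmentation literature), not the area under a PR curve.

Two matching policies are provided.  ``one_to_one`` (default) greedily
matches pairs by descending IoU with each instance used at most once — the
standard convention in instance-segmentation benchmarks.  ``literal``
counts each predicted mask as TP when *some* ground-truth mask exceeds T
and each ground-truth mask as FN when no prediction exceeds T; the two
policies agree whenever no instance overlaps two others above threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .image import validate_label_mask

#: Default IoU threshold grid, 0.1 (lenient overlap) to 0.7 (strict).
DEFAULT_THRESHOLDS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7)

METRIC_COLUMNS = ("threshold", "tp", "fp", "fn", "precision", "recall", "average_precision", "f1")


class Metrics(NamedTuple):
    precision: float
    recall: float
    average_precision: float
    f1: float


@dataclass
class MatchTable:
    """Matched and unmatched instances at one IoU threshold."""

    matches: list[tuple[int, int, float]]  # (gt_id, pred_id, iou)
    unmatched_gt: list[int]
    unmatched_pred: list[int]
    threshold: float
    policy: str

    @property
    def tp(self) -> int:
        return len(self.matches)

    @property
    def fp(self) -> int:
        return len(self.unmatched_pred)

    @property
    def fn(self) -> int:
        return len(self.unmatched_gt)


def instance_iou(gt_instance: np.ndarray, pred_instance: np.ndarray) -> float:
    """IoU of two boolean pixel masks (or anything truthy per pixel)."""
    a = np.asarray(gt_instance, dtype=bool)
    b = np.asarray(pred_instance, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 or nb == 0:
        raise ValueError("instance masks must be nonempty")
    inter = int(np.logical_and(a, b).sum())
    return inter / (na + nb - inter)


def _overlap_pairs(gt: np.ndarray, pred: np.ndarray):
    """All (gt_id, pred_id, iou) pairs with nonzero pixel overlap, plus areas."""
    gt_flat = gt.ravel()
    pred_flat = pred.ravel()
    gt_areas = dict(zip(*np.unique(gt_flat[gt_flat > 0], return_counts=True)))
    pred_areas = dict(zip(*np.unique(pred_flat[pred_flat > 0], return_counts=True)))
    both = (gt_flat > 0) & (pred_flat > 0)
    pairs: list[tuple[int, int, float]] = []
    if both.any():
        combined = gt_flat[both].astype(np.int64) * (pred_flat.max() + 1) + pred_flat[both]
        uniq, counts = np.unique(combined, return_counts=True)
        base = int(pred_flat.max() + 1)
        for code, inter in zip(uniq, counts):
            g, p = int(code // base), int(code % base)
            union = gt_areas[g] + pred_areas[p] - inter
            pairs.append((g, p, float(inter / union)))
    return pairs, sorted(int(i) for i in gt_areas), sorted(int(i) for i in pred_areas)


def match_instances(
    gt: np.ndarray, pred: np.ndarray, threshold: float, policy: str = "one_to_one"
) -> MatchTable:
    """Match predicted to ground-truth instances at IoU > ``threshold``.

    Ties at exactly ``threshold`` count as non-matches (strict inequality).
    Greedy one-to-one matching breaks IoU ties by lower ground-truth id,
    then lower prediction id, for determinism.
    """
    gt = validate_label_mask(gt)
    pred = validate_label_mask(pred, shape=gt.shape)
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if policy not in ("one_to_one", "literal"):
        raise ValueError(f"unknown policy {policy!r}")

    pairs, gt_ids, pred_ids = _overlap_pairs(gt, pred)
    if policy == "one_to_one":
        used_gt: set[int] = set()
        used_pred: set[int] = set()
        matches: list[tuple[int, int, float]] = []
        for g, p, iou in sorted(pairs, key=lambda r: (-r[2], r[0], r[1])):
            if iou <= threshold:
                break
            if g in used_gt or p in used_pred:
                continue
            matches.append((g, p, iou))
            used_gt.add(g)
            used_pred.add(p)
        unmatched_gt = [g for g in gt_ids if g not in used_gt]
        unmatched_pred = [p for p in pred_ids if p not in used_pred]
    else:
        best_for_pred: dict[int, tuple[int, float]] = {}
        best_for_gt: dict[int, float] = {}
        for g, p, iou in pairs:
            if p not in best_for_pred or iou > best_for_pred[p][1]:
                best_for_pred[p] = (g, iou)
            best_for_gt[g] = max(best_for_gt.get(g, 0.0), iou)
        matches = [
            (g, p, iou) for p, (g, iou) in sorted(best_for_pred.items()) if iou > threshold
        ]
        matched_preds = {p for _, p, _ in matches}
        unmatched_pred = [p for p in pred_ids if p not in matched_preds]
        unmatched_gt = [g for g in gt_ids if best_for_gt.get(g, 0.0) <= threshold]
    return MatchTable(matches, unmatched_gt, unmatched_pred, threshold, policy)


def compute_metrics(tp: int, fp: int, fn: int) -> Metrics:
    """Precision, recall, average precision, and F1 from detection counts.

    Any 0/0 ratio is defined as 0 (with a warning): an empty field scored
    against an empty prediction yields all-zero metrics rather than NaN.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name}: 0/0 defined as 0", RuntimeWarning, stacklevel=3)
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    ap = ratio(tp, tp + fn + fp, "average_precision")
    f1 = ratio(2 * precision * recall, precision + recall, "f1")
    return Metrics(precision, recall, ap, f1)


def evaluate_curve(
    gt: np.ndarray,
    pred: np.ndarray,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    policy: str = "one_to_one",
) -> pd.DataFrame:
    """TP/FP/FN and all four metrics at every threshold of the grid."""
    _check_grid(thresholds)
    rows = []
    for t in thresholds:
        m = match_instances(gt, pred, t, policy=policy)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            metrics = compute_metrics(m.tp, m.fp, m.fn)
        rows.append((t, m.tp, m.fp, m.fn, *metrics))
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def evaluate_set(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    policy: str = "one_to_one",
) -> tuple[pd.DataFrame, list[pd.DataFrame]]:
    """Evaluate several (gt, pred) mask pairs against one grid.

    Counts are pooled across images before computing metrics (micro
    aggregation, the default when a test set is scored as one pool); the
    per-image curves are also returned so a macro mean can be formed.
    """
    _check_grid(thresholds)
    if not pairs:
        raise ValueError("no mask pairs to evaluate")
    per_image = [evaluate_curve(g, p, thresholds, policy) for g, p in pairs]
    pooled_rows = []
    for i, t in enumerate(thresholds):
        tp = int(sum(c["tp"].iloc[i] for c in per_image))
        fp = int(sum(c["fp"].iloc[i] for c in per_image))
        fn = int(sum(c["fn"].iloc[i] for c in per_image))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            metrics = compute_metrics(tp, fp, fn)
        pooled_rows.append((t, tp, fp, fn, *metrics))
    return pd.DataFrame(pooled_rows, columns=METRIC_COLUMNS), per_image


def _check_grid(thresholds: Sequence[float]) -> None:
    arr = np.asarray(thresholds, dtype=float)
    if arr.size == 0:
        raise ValueError("threshold grid is empty")
    if (arr <= 0).any() or (arr > 1).any():
        raise ValueError("thresholds must lie in (0, 1]")
    if (np.diff(arr) <= 0).any():
        raise ValueError("thresholds must be strictly increasing")
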