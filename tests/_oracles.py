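"""Independent brute-force reference implementations used as test oracles.

These operate on explicit per-instance pixel *sets* (frozensets of (row,
col) tuples) with direct set arithmetic — a deliberately different route
from the array/histogram implementation in the package — so that agreement
between the two is meaningful.
"""

from __future__ import annotations

import numpy as np
from skimage.draw import disk


def pixel_sets(mask: np.ndarray) -> dict[int, frozenset]:
    out = {}
    for i in np.unique(mask):
        if i > 0:
            out[int(i)] = frozenset(zip(*np.where(mask == i)))
    return out


def brute_iou(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b)


def brute_counts(gt_mask: np.ndarray, pred_mask: np.ndarray, t: float, policy: str = "one_to_one"):
    """TP/FP/FN by direct set arithmetic and explicit greedy/literal matching."""
    g = pixel_sets(gt_mask)
    p = pixel_sets(pred_mask)
    pairs = [
        (gi, pi, brute_iou(gs, ps))
        for gi, gs in g.items()
        for pi, ps in p.items()
        if gs & ps
    ]
    if policy == "one_to_one":
        used_g: set[int] = set()
        used_p: set[int] = set()
        for gi, pi, iou in sorted(pairs, key=lambda r: (-r[2], r[0], r[1])):
            if iou <= t:
                break
            if gi in used_g or pi in used_p:
                continue
            used_g.add(gi)
            used_p.add(pi)
        tp = len(used_g)
        fp = len(p) - len(used_p)
        fn = len(g) - len(used_g)
    elif policy == "literal":
        tp = sum(
            1 for pi in p if any(iou > t for gi, pj, iou in pairs if pj == pi)
        )
        fp = len(p) - tp
        fn = sum(
            1 for gi in g if not any(iou > t for gj, pi, iou in pairs if gj == gi)
        )
    else:
        raise ValueError(policy)
    return tp, fp, fn


def brute_metrics(tp: int, fp: int, fn: int) -> tuple[float, float, float, float]:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    ap = tp / (tp + fn + fp) if tp + fn + fp else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, ap, f1


def random_mask_pair(
    rng: np.random.Generator, shape=(64, 64), max_instances: int = 12
) -> tuple[np.ndarray, np.ndarray]:
    """A random ground-truth mask and a perturbed prediction of it.

    Perturbations: per-instance jitter, occasional drops, occasional
    spurious extra instances; later paint wins overlapping pixels.
    """
    gt = np.zeros(shape, dtype=np.int32)
    n = int(rng.integers(1, max_instances + 1))
    for i in range(1, n + 1):
        r, c = rng.integers(5, shape[0] - 5, size=2)
        rr, cc = disk((int(r), int(c)), int(rng.integers(2, 6)), shape=shape)
        gt[rr, cc] = i
    pred = np.zeros(shape, dtype=np.int32)
    next_label = 1
    for i in range(1, n + 1):
        if rng.random() < 0.1:
            continue  # missed instance
        rows, cols = np.where(gt == i)
        if rows.size == 0:
            continue
        dr, dc = rng.integers(-3, 4, size=2)
        pred[np.clip(rows + dr, 0, shape[0] - 1), np.clip(cols + dc, 0, shape[1] - 1)] = next_label
        next_label += 1
    if rng.random() < 0.3:  # spurious detection
        r, c = rng.integers(5, shape[0] - 5, size=2)
        rr, cc = disk((int(r), int(c)), int(rng.integers(2, 5)), shape=shape)
        pred[rr, cc] = next_label
    return gt, pred
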