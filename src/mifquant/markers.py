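"""Per-nucleus marker positivity: features, thresholding, few-shot learning.

Membrane and cytoplasmic markers (CD11c, CD40, ...) do not stain the
nucleus itself, so each cell's signal is measured over the nucleus plus a
perinuclear ring — a morphological dilation of the nucleus with contested
pixels assigned to the nearer nucleus.  Two classification routes are
provided, mirroring common annotation practice:

* *thresholding*: a cell is positive when at least a given fraction of its
  (nucleus ∪ ring) pixels exceed an intensity threshold;
* *few-shot logistic regression*: the analyst marks a handful of positive
  and negative exemplar nuclei (typically 5-10 each) and a ridge-penalised
  logistic regression on three standardised intensity features classifies
  the rest, with an optional refine step that folds corrected cells back
  into the exemplar set and refits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.segmentation import expand_labels
from sklearn.linear_model import LogisticRegression

from .image import ALL_MARKERS, MultiplexImage, label_ids, validate_label_mask

FEATURE_SUFFIXES = ("nuc_mean", "ring_mean", "frac_above")


def _safe_region_mean(values: np.ndarray, regions: np.ndarray, ids: np.ndarray) -> np.ndarray:
    """Per-label mean that returns 0 for labels with no pixels in ``regions``."""
    counts = ndimage.sum_labels(np.ones_like(values), regions, ids)
    sums = ndimage.sum_labels(values, regions, ids)
    return np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)


def extract_features(
    image: MultiplexImage,
    labels: np.ndarray,
    *,
    ring_width: int = 3,
    markers: Sequence[str] | None = None,
    ref_intensity: Mapping[str, float] | float | None = None,
) -> pd.DataFrame:
    """Per-cell intensity features for every marker channel.

    For each nucleus the ring is ``expand_labels(labels, ring_width)`` minus
    the nucleus; ``expand_labels`` assigns contested pixels between adjacent
    cells to the nearer nucleus.  Features per marker: mean intensity inside
    the nucleus, mean in the ring, mean over the union (``cell_mean``, the
    per-cell MFI), and the fraction of union pixels above a reference
    intensity (per-channel Otsu when not supplied).

    The reference intensities used are recorded in ``result.attrs``.
    """
    labels = validate_label_mask(labels, shape=image.shape)
    if ring_width < 0:
        raise ValueError("ring_width must be >= 0")
    markers = tuple(markers) if markers is not None else tuple(
        n for n in image.names if n in ALL_MARKERS
    )
    ids = label_ids(labels)
    expanded = expand_labels(labels, distance=ring_width) if ring_width > 0 else labels
    rings = np.where(labels == 0, expanded, 0)
    union = np.where(labels > 0, labels, rings)

    areas = ndimage.sum_labels(np.ones_like(labels, dtype=float), labels, ids)
    com = ndimage.center_of_mass(np.ones_like(labels, dtype=float), labels, ids) if len(ids) else []
    com = np.asarray(com, dtype=float).reshape(len(ids), 2)

    data: dict[str, np.ndarray] = {
        "cell_id": ids.astype(np.int64),
        "area": areas,
        "centroid_row": com[:, 0] if len(ids) else np.array([]),
        "centroid_col": com[:, 1] if len(ids) else np.array([]),
    }
    refs: dict[str, float] = {}
    for marker in markers:
        channel = image[marker]
        if ref_intensity is None:
            ref = float(threshold_otsu(channel)) if np.ptp(channel) > 0 else 0.0
        elif isinstance(ref_intensity, Mapping):
            if marker not in ref_intensity:
                raise KeyError(f"ref_intensity missing marker {marker!r}")
            ref = float(ref_intensity[marker])
        else:
            ref = float(ref_intensity)
        refs[marker] = ref
        data[f"{marker}_nuc_mean"] = _safe_region_mean(channel, labels, ids)
        data[f"{marker}_ring_mean"] = _safe_region_mean(channel, rings, ids)
        data[f"{marker}_cell_mean"] = _safe_region_mean(channel, union, ids)
        data[f"{marker}_frac_above"] = _safe_region_mean(
            (channel > ref).astype(float), union, ids
        )
    table = pd.DataFrame(data)
    table.attrs["ring_width"] = ring_width
    table.attrs["ref_intensity"] = refs
    return table


def classify_by_threshold(
    features: pd.DataFrame,
    marker: str,
    intensity_threshold: float | None = None,
    pixel_fraction: float = 0.2,
) -> pd.Series:
    """Positive call when >= ``pixel_fraction`` of cell pixels exceed the threshold.

    The pixel fractions were computed at feature-extraction time against a
    recorded reference intensity; passing a different ``intensity_threshold``
    here is an error (re-extract features at the desired threshold instead).
    """
    col = f"{marker}_frac_above"
    if col not in features.columns:
        raise KeyError(f"unknown marker {marker!r}: no column {col}")
    if not 0.0 <= pixel_fraction <= 1.0:
        raise ValueError("pixel_fraction must be in [0, 1]")
    recorded = features.attrs.get("ref_intensity", {}).get(marker)
    if intensity_threshold is not None and recorded is not None:
        if abs(intensity_threshold - recorded) > 1e-9:
            raise ValueError(
                f"features were extracted at reference intensity {recorded}, not "
                f"{intensity_threshold}; re-run extract_features with "
                f"ref_intensity={intensity_threshold}"
            )
    calls = features[col] >= pixel_fraction
    calls.name = marker
    return calls


@dataclass
class MarkerClassifier:
    """A fitted few-shot logistic-regression marker classifier."""

    marker: str
    feature_columns: tuple[str, ...]
    scale_mean: np.ndarray
    scale_std: np.ndarray
    coef: np.ndarray
    intercept: float
    positive_ids: tuple[int, ...]
    negative_ids: tuple[int, ...]
    cutoff: float = 0.5

    def decision(self, features: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_columns if c not in features.columns]
        if missing:
            raise KeyError(f"features missing columns {missing}")
        x = (features[list(self.feature_columns)].to_numpy() - self.scale_mean) / self.scale_std
        return x @ self.coef + self.intercept

    def to_dict(self) -> dict:
        return {
            "marker": self.marker,
            "feature_columns": list(self.feature_columns),
            "scale_mean": self.scale_mean.tolist(),
            "scale_std": self.scale_std.tolist(),
            "coef": self.coef.tolist(),
            "intercept": float(self.intercept),
            "positive_ids": list(self.positive_ids),
            "negative_ids": list(self.negative_ids),
            "cutoff": self.cutoff,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MarkerClassifier":
        return cls(
            marker=d["marker"],
            feature_columns=tuple(d["feature_columns"]),
            scale_mean=np.asarray(d["scale_mean"], dtype=float),
            scale_std=np.asarray(d["scale_std"], dtype=float),
            coef=np.asarray(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
            positive_ids=tuple(d["positive_ids"]),
            negative_ids=tuple(d["negative_ids"]),
            cutoff=float(d.get("cutoff", 0.5)),
        )


def _feature_columns(marker: str) -> tuple[str, ...]:
    return tuple(f"{marker}_{s}" for s in FEATURE_SUFFIXES)


def train_marker_classifier(
    features: pd.DataFrame,
    positive_ids: Sequence[int],
    negative_ids: Sequence[int],
    marker: str,
    *,
    ridge_c: float = 1.0,
    cutoff: float = 0.5,
) -> MarkerClassifier:
    """Fit a logistic regression on exemplar nuclei.

    Features (nucleus mean, ring mean, above-threshold fraction) are
    standardised on the exemplars; a small ridge penalty keeps the fit
    stable in the 5-10 exemplar regime.  The fit is deterministic for fixed
    inputs.
    """
    pos = [int(i) for i in positive_ids]
    neg = [int(i) for i in negative_ids]
    if not pos or not neg:
        raise ValueError("both classes required: give positive and negative exemplars")
    overlap = set(pos) & set(neg)
    if overlap:
        raise ValueError(f"ids in both classes: {sorted(overlap)}")
    index = features.set_index("cell_id")
    missing = [i for i in pos + neg if i not in index.index]
    if missing:
        raise KeyError(f"exemplar ids not in feature table: {missing}")

    cols = _feature_columns(marker)
    absent = [c for c in cols if c not in features.columns]
    if absent:
        raise KeyError(f"unknown marker {marker!r}: missing columns {absent}")

    x = index.loc[pos + neg, list(cols)].to_numpy(dtype=float)
    y = np.array([1] * len(pos) + [0] * len(neg))
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std[std == 0] = 1.0
    model = LogisticRegression(C=ridge_c, solver="lbfgs", max_iter=1000)
    model.fit((x - mean) / std, y)
    return MarkerClassifier(
        marker=marker,
        feature_columns=cols,
        scale_mean=mean,
        scale_std=std,
        coef=model.coef_.ravel(),
        intercept=float(model.intercept_[0]),
        positive_ids=tuple(pos),
        negative_ids=tuple(neg),
        cutoff=cutoff,
    )


def apply_marker_classifier(
    classifier: MarkerClassifier, features: pd.DataFrame
) -> tuple[pd.Series, pd.Series]:
    """Return (boolean calls, probabilities) for every cell in the table.

    Training exemplars keep their annotated class regardless of the model
    probability, matching the annotation workflow in which user labels are
    authoritative.
    """
    z = classifier.decision(features)
    probs = 1.0 / (1.0 + np.exp(-z))
    calls = probs >= classifier.cutoff
    ids = features["cell_id"].to_numpy()
    calls[np.isin(ids, classifier.positive_ids)] = True
    calls[np.isin(ids, classifier.negative_ids)] = False
    return (
        pd.Series(calls, index=features.index, name=classifier.marker),
        pd.Series(probs, index=features.index, name=f"{classifier.marker}_prob"),
    )


def refine_classifier(
    classifier: MarkerClassifier,
    features: pd.DataFrame,
    corrections: Mapping[int, bool],
) -> MarkerClassifier:
    """Fold user-corrected cells into the exemplar set and refit.

    A correction overrides any previous exemplar assignment of that cell.
    """
    pos = [i for i in classifier.positive_ids if not (i in corrections and not corrections[i])]
    neg = [i for i in classifier.negative_ids if not (i in corrections and corrections[i])]
    for cid, is_pos in corrections.items():
        target = pos if is_pos else neg
        if cid not in target:
            target.append(int(cid))
    return train_marker_classifier(
        features, pos, neg, classifier.marker, cutoff=classifier.cutoff
    )


def classifier_distance_to_truth(
    calls: pd.Series | np.ndarray, truth: pd.Series | np.ndarray, total_cells: int
) -> float:
    """Absolute population-percentage error of a classifier, in points.

    Both the predicted and the true positive counts are converted to
    percentages of ``total_cells`` (all nucleated cells in the field) and
    the absolute difference returned.
    """
    if total_cells <= 0:
        raise ValueError("total_cells must be positive")
    pred_pct = 100.0 * float(np.asarray(calls, dtype=bool).sum()) / total_cells
    true_pct = 100.0 * float(np.asarray(truth, dtype=bool).sum()) / total_cells
    return abs(pred_pct - true_pct)
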