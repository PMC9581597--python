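"""Nuclei instance segmentation: a classical baseline plus mask import.

Deep-learning segmenters (Stardist, SplineDist, Cellpose, three-class
U-Nets) live outside this package; their outputs enter through
:func:`import_external_labels` as ordinary label masks and can then be
benchmarked with :mod:`mifquant.seg_eval`.  The in-repo baseline is a
marker-controlled watershed on the smoothed nuclear channel — enough to run
the full pipeline end to end on a workstation with no GPU.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import relabel_sequential, watershed

from .image import ImageValidationError, MultiplexImage, validate_label_mask
from .io import read_labels


def segment_nuclei_baseline(
    nuclei: np.ndarray,
    *,
    smoothing_sigma: float = 2.0,
    threshold: float | str = "otsu",
    min_area: int = 30,
    seed_distance: int = 5,
) -> np.ndarray:
    """Segment nuclei by thresholding plus marker-controlled watershed.

    The nuclear channel is Gaussian-smoothed, thresholded (Otsu by default,
    or a fixed intensity), and split into instances by a watershed on the
    negated distance transform seeded at distance-transform peaks at least
    ``seed_distance`` pixels apart (nearby peaks merge into one seed).
    Instances under ``min_area`` pixels are dropped and labels are
    relabelled consecutively from 1.  An empty foreground returns a valid
    all-zero mask.
    """
    img = np.asarray(nuclei, dtype=float)
    if img.ndim != 2:
        raise ValueError("nuclei raster must be 2D")
    smoothed = gaussian(img, sigma=smoothing_sigma, preserve_range=True)
    if threshold == "otsu":
        if np.ptp(smoothed) == 0:
            return np.zeros(img.shape, dtype=np.int32)
        thr = threshold_otsu(smoothed)
    else:
        thr = float(threshold)
    foreground = smoothed > thr
    if not foreground.any():
        return np.zeros(img.shape, dtype=np.int32)

    distance = ndimage.distance_transform_edt(foreground)
    peaks = peak_local_max(
        distance, min_distance=seed_distance, labels=foreground, exclude_border=False
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = 1
    # Peaks closer than seed_distance collapse into one marker component.
    markers = cc_label(
        ndimage.binary_dilation(markers, iterations=max(seed_distance // 2, 1)) & foreground
    )
    if markers.max() == 0:
        markers = cc_label(foreground)
    labels = watershed(-distance, markers=markers, mask=foreground)
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < min_area)
    labels[np.isin(labels, small[small > 0])] = 0
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def import_external_labels(
    path, image: MultiplexImage | None = None, *, relabel: bool = False
) -> np.ndarray:
    """Load a label mask produced by an external segmenter and validate it.

    When ``image`` is given the mask shape must match its pixel grid.  With
    ``relabel=True`` arbitrary instance ids are mapped onto 1..n, preserving
    the partition of the foreground.
    """
    mask = read_labels(path)
    if image is not None and mask.shape != image.shape:
        raise ImageValidationError(
            f"mask shape {mask.shape} does not match image shape {image.shape}"
        )
    if relabel:
        mask, _, _ = relabel_sequential(mask)
    return validate_label_mask(mask)
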