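"""Core raster containers for multiplexed immunofluorescence fields.

A field of view is represented as a :class:`MultiplexImage` — a stack of
named single-channel 2D rasters sharing one pixel grid — plus, where nuclei
have been segmented, an integer *label mask* in which 0 is background and
each nucleus carries a unique positive id.  Coordinates are 0-based and
row-major throughout; masks are pixel-area masks (a pixel belongs to the
instance whose id it stores).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

#: Name of the nuclear-stain channel (Hoechst-like) used for segmentation
#: and inter-round registration.
NUCLEI_CHANNEL = "nuclei"

#: Lineage identity markers: a cell positive for all three is gated as a
#: conventional type 1 dendritic cell (cDC1).
IDENTITY_MARKERS = ("CD11c", "HLA-DR", "BDCA-3")

#: Costimulatory / checkpoint markers defining the four cDC1 subsets.
CHECKPOINT_MARKERS = ("CD40", "PD-L1")

#: Functional (activator vs tolerogenic) markers.
FUNCTIONAL_MARKERS = ("IL-12", "CD86", "IDO")

ALL_MARKERS = IDENTITY_MARKERS + CHECKPOINT_MARKERS + FUNCTIONAL_MARKERS
DEFAULT_CHANNELS = (NUCLEI_CHANNEL,) + ALL_MARKERS

#: Markers imaged in the first staining round (together with nuclei).
ROUND1_MARKERS = IDENTITY_MARKERS + CHECKPOINT_MARKERS
#: Markers imaged in the second staining round (together with nuclei).
ROUND2_MARKERS = FUNCTIONAL_MARKERS


class ImageValidationError(ValueError):
    """Raised when a raster violates a container invariant."""


@dataclass
class MultiplexImage:
    """A registered stack of named 2D intensity channels for one field.

    Parameters
    ----------
    channels
        Mapping from channel name to a 2D non-negative float raster.  All
        channels must share one shape.  Intensities are in arbitrary
        fluorescence units.
    round_id
        Staining round the stack was acquired in (1-based).
    metadata
        Free-form provenance (registration transform, generator seed, ...).
    """

    channels: dict[str, np.ndarray]
    round_id: int = 1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ImageValidationError("MultiplexImage requires at least one channel")
        coerced: dict[str, np.ndarray] = {}
        shape = None
        for name, raster in self.channels.items():
            arr = np.asarray(raster, dtype=np.float64)
            if arr.ndim != 2:
                raise ImageValidationError(
                    f"channel {name!r} is {arr.ndim}D; channels must be 2D"
                )
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ImageValidationError(
                    f"channel {name!r} has shape {arr.shape}, expected {shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ImageValidationError(f"channel {name!r} contains non-finite values")
            if arr.min() < 0:
                raise ImageValidationError(f"channel {name!r} contains negative intensities")
            coerced[name] = arr
        self.channels = coerced

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.channels)

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"unknown channel {name!r}; have {list(self.channels)}")
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def __iter__(self) -> Iterator[str]:
        return iter(self.channels)

    def subset(self, names: Mapping[str, None] | tuple[str, ...] | list[str]) -> "MultiplexImage":
        """Return a new stack restricted to ``names`` (order preserved)."""
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise KeyError(f"unknown channels {missing}; have {list(self.channels)}")
        return MultiplexImage(
            {n: self.channels[n].copy() for n in names},
            round_id=self.round_id,
            metadata=dict(self.metadata),
        )


def validate_label_mask(mask: np.ndarray, *, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Validate and coerce an instance label mask to int32.

    ``mask`` must be a 2D raster of non-negative integers (0 = background).
    Float inputs are accepted only when every value is integral.
    """
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ImageValidationError(f"label mask must be 2D, got {arr.ndim}D")
    if shape is not None and arr.shape != shape:
        raise ImageValidationError(f"label mask shape {arr.shape} != image shape {shape}")
    if np.issubdtype(arr.dtype, np.floating):
        if not np.all(np.isfinite(arr)) or not np.all(arr == np.round(arr)):
            raise ImageValidationError("label mask contains non-integer values")
        arr = arr.astype(np.int64)
    elif not np.issubdtype(arr.dtype, np.integer):
        raise ImageValidationError(f"label mask dtype {arr.dtype} is not integer")
    if arr.min() < 0:
        raise ImageValidationError("label mask contains negative labels")
    return arr.astype(np.int32)


def label_ids(mask: np.ndarray) -> np.ndarray:
    """Sorted array of positive instance ids present in ``mask``."""
    ids = np.unique(mask)
    return ids[ids > 0]
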