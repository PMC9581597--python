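"""Phenotype gating, abundances, subset fractions, and MFI summaries.

Marker calls compose hierarchically into populations: the cDC1 identity
gate (CD11c+ HLA-DR+ BDCA-3+), the four CD40/PD-L1 checkpoint subsets
within cDC1s, and the eight IL-12/CD86/IDO functional combinations within
each checkpoint subset.  Abundances are reported as percentages of all
nucleated cells in the field; subset fractions as percentages of their
parent population; expression levels as background-normalised mean
fluorescence intensity (MFI) on a log10 scale, optionally split into
high/low expressers at a pooled Otsu (or median) cutpoint.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.segmentation import expand_labels

from .image import CHECKPOINT_MARKERS, FUNCTIONAL_MARKERS, IDENTITY_MARKERS, MultiplexImage


class GatingError(ValueError):
    """Raised when a gating schema references markers without calls."""


@dataclass(frozen=True)
class Population:
    """A named population: a conjunction of marker requirements under a parent."""

    requires: Mapping[str, bool]
    parent: str | None = None


@dataclass
class GatingSchema:
    """Named populations as boolean marker expressions with a hierarchy."""

    populations: dict[str, Population] = field(default_factory=dict)

    def add(self, name: str, requires: Mapping[str, bool], parent: str | None = None) -> None:
        if parent is not None and parent not in self.populations:
            raise GatingError(f"parent {parent!r} of {name!r} is not declared")
        self.populations[name] = Population(dict(requires), parent)

    def markers(self) -> set[str]:
        out: set[str] = set()
        for pop in self.populations.values():
            out.update(pop.requires)
        return out


def _subset_name(markers: Sequence[str], signs: Sequence[bool]) -> str:
    return "".join(f"{m}{'+' if s else '-'}" for m, s in zip(markers, signs))


def default_cdc1_schema(functional: bool = True) -> GatingSchema:
    """The standard cDC1 gating tree.

    cDC1 = CD11c+ HLA-DR+ BDCA-3+; below it the fourfold CD40/PD-L1 subsets
    and (optionally) the eight IL-12/CD86/IDO combinations under each
    checkpoint subset, named e.g. ``cDC1/CD40+PD-L1-/IL-12+CD86+IDO-``.
    """
    schema = GatingSchema()
    schema.add("cDC1", {m: True for m in IDENTITY_MARKERS})
    for signs in itertools.product([True, False], repeat=2):
        subset = f"cDC1/{_subset_name(CHECKPOINT_MARKERS, signs)}"
        schema.add(subset, dict(zip(CHECKPOINT_MARKERS, signs)), parent="cDC1")
        if functional:
            for fsigns in itertools.product([True, False], repeat=3):
                name = f"{subset}/{_subset_name(FUNCTIONAL_MARKERS, fsigns)}"
                schema.add(name, dict(zip(FUNCTIONAL_MARKERS, fsigns)), parent=subset)
    return schema


def gate_cells(cell_table: pd.DataFrame, schema: GatingSchema) -> pd.DataFrame:
    """Boolean membership column per population; children imply their parents.

    ``cell_table`` must carry one boolean call column per marker the schema
    references.  Gating is a pure function of the calls: idempotent and
    independent of declaration order (the hierarchy is resolved topologically
    through the parent links).
    """
    missing = sorted(m for m in schema.markers() if m not in cell_table.columns)
    if missing:
        raise GatingError(f"cell table lacks marker calls for {missing}")
    members = pd.DataFrame(index=cell_table.index)

    def resolve(name: str) -> pd.Series:
        if name in members.columns:
            return members[name]
        pop = schema.populations[name]
        mask = pd.Series(True, index=cell_table.index)
        for marker, wanted in pop.requires.items():
            mask &= cell_table[marker].astype(bool) == wanted
        if pop.parent is not None:
            mask &= resolve(pop.parent)
        members[name] = mask
        return mask

    for name in schema.populations:
        resolve(name)
    return members


def population_abundance(membership: pd.Series | np.ndarray, total_nucleated: int) -> float:
    """Population size as a percentage of all nucleated cells in the field."""
    if total_nucleated <= 0:
        raise ValueError("total_nucleated must be positive")
    return 100.0 * float(np.asarray(membership, dtype=bool).sum()) / total_nucleated


@dataclass
class SubsetFractions:
    """Subset composition of a parent population, in percent."""

    counts: pd.Series
    fractions_pct: pd.Series
    parent_size: int
    defined: bool


def subset_fractions(
    parent_members: pd.Series, subset_memberships: pd.DataFrame
) -> SubsetFractions:
    """Fractions of a parent population across subsets that partition it.

    Raises if the subsets do not partition the parent (every parent member
    in exactly one subset).  An empty parent yields a flagged, undefined
    result rather than NaN percentages.
    """
    parent = parent_members.astype(bool)
    subs = subset_memberships.astype(bool)
    inside = subs.loc[parent]
    if len(inside) and not (inside.sum(axis=1) == 1).all():
        bad = inside.index[inside.sum(axis=1) != 1].tolist()[:5]
        raise ValueError(f"subsets do not partition the parent (cells {bad} ...)")
    if subs.loc[~parent].any().any():
        raise ValueError("subset members found outside the parent population")
    counts = inside.sum(axis=0)
    n = int(parent.sum())
    if n == 0:
        return SubsetFractions(counts, pd.Series(np.nan, index=counts.index), 0, defined=False)
    fractions = 100.0 * counts / n
    assert abs(fractions.sum() - 100.0) < 1e-9
    return SubsetFractions(counts, fractions, n, defined=True)


def estimate_background(
    image: MultiplexImage, labels: np.ndarray, marker: str, *, ring_width: int = 3
) -> float:
    """Median marker intensity outside all nuclei and their rings.

    Serves as the per-image normalisation constant for MFI reporting,
    removing the field's illumination/background scale.
    """
    expanded = expand_labels(labels, distance=ring_width)
    outside = image[marker][expanded == 0]
    if outside.size == 0:
        raise ValueError("no background pixels outside cells")
    return float(np.median(outside))


@dataclass
class MFISummary:
    """Log10 normalised per-cell MFI of one marker in one population."""

    population: str
    marker: str
    cell_ids: np.ndarray
    log10_mfi: np.ndarray
    normalization: float
    n_excluded_nonpositive: int
    high: np.ndarray | None = None  # boolean per retained cell
    cutpoint: float | None = None
    degenerate: bool = False


def mfi_summary(
    cell_table: pd.DataFrame,
    membership: pd.Series,
    marker: str,
    normalization: float,
    *,
    population: str = "",
) -> MFISummary:
    """Per-cell normalised MFI (log10) for a population.

    Per-cell MFI is the mean intensity over nucleus ∪ ring
    (``<marker>_cell_mean`` from feature extraction) divided by the
    per-image ``normalization`` constant; non-positive normalised values
    are excluded and counted.
    """
    col = f"{marker}_cell_mean"
    if col not in cell_table.columns:
        raise KeyError(f"cell table lacks column {col}")
    if normalization <= 0:
        raise ValueError("normalization must be positive")
    sel = cell_table.loc[membership.astype(bool)]
    if sel.empty:
        raise ValueError(f"population {population or '<unnamed>'} is empty")
    values = sel[col].to_numpy(dtype=float) / normalization
    keep = values > 0
    return MFISummary(
        population=population,
        marker=marker,
        cell_ids=sel["cell_id"].to_numpy()[keep],
        log10_mfi=np.log10(values[keep]),
        normalization=normalization,
        n_excluded_nonpositive=int((~keep).sum()),
    )


def split_high_low(values: np.ndarray, method: str = "otsu") -> tuple[np.ndarray, float, bool]:
    """Split expression values into high/low at a data-driven cutpoint.

    ``otsu`` (default) places the cutpoint by Otsu's criterion on the
    pooled values — pool across all compared groups before calling so one
    uniform cutpoint applies to every group; ``median`` uses the pooled
    median.  Returns ``(is_high, cutpoint, degenerate)``; identical values
    are flagged degenerate and all assigned low.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values to split")
    if np.ptp(arr) == 0:
        return np.zeros(arr.size, dtype=bool), float(arr[0]), True
    if method == "otsu":
        cut = float(threshold_otsu(arr))
    elif method == "median":
        cut = float(np.median(arr))
    else:
        raise ValueError(f"unknown method {method!r}")
    return arr > cut, cut, False


def emulate_visual_scoring(
    cell_table: pd.DataFrame,
    membership: pd.Series,
    n_sample: int = 100,
    seed: int = 0,
) -> float:
    """Estimate a population percentage from a small uniform cell sample.

    Emulates manual visual scoring, which counts a fixed number of cells
    (conventionally 100) per field instead of the full census: draws
    ``n_sample`` cells without replacement and reports the population
    percentage within the sample.
    """
    n_total = len(cell_table)
    if n_sample > n_total:
        raise ValueError(f"n_sample={n_sample} exceeds total cells {n_total}")
    if n_sample <= 0:
        raise ValueError("n_sample must be positive")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n_total, size=n_sample, replace=False)
    picked = membership.astype(bool).to_numpy()[idx]
    return 100.0 * float(picked.sum()) / n_sample
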