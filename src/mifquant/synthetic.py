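"""Synthetic multiplexed immunofluorescence fields with known ground truth.

Real melanoma fields carry on the order of a thousand to two thousand
touching, roughly convex nuclei per image; each nucleus belongs to a cell
whose marker phenotype follows a hierarchical mixture — a cDC1 fraction
(CD11c+ HLA-DR+ BDCA-3+), a fourfold CD40/PD-L1 subset split within cDC1s,
and IL-12/CD86/IDO functional combinations within each subset.  The
generator emulates exactly that structure:

* nuclei are convex ellipses with truncated-normal radii, placed uniformly
  with touching allowed (later placement wins contested pixels);
* the nuclear channel renders nucleus interiors; each marker channel is a
  perinuclear ring (membrane/cytoplasmic stain) scaled by the cell's true
  amplitude;
* amplitudes follow a two-mode log-normal law (a dim mode for negative
  cells, a bright mode for positive cells) on top of additive background
  and Gaussian read noise clipped at zero;
* a second staining round can be derived from the same scene under a known
  rigid displacement with fresh noise, for registration tests.

Every draw is threaded from one integer seed through a fixed
``numpy.random.SeedSequence`` spawn order (phenotypes, geometry, noise), so
equal seeds give bit-identical scenes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import ellipse
from skimage.segmentation import expand_labels

from .image import (
    ALL_MARKERS,
    FUNCTIONAL_MARKERS,
    IDENTITY_MARKERS,
    NUCLEI_CHANNEL,
    ROUND2_MARKERS,
    MultiplexImage,
)
from .registration import RigidTransform, apply_transform

#: CD40/PD-L1 subset names conditional on cDC1, in fixed sampling order.
CHECKPOINT_SUBSETS = ("CD40+PD-L1+", "CD40+PD-L1-", "CD40-PD-L1+", "CD40-PD-L1-")
_SUBSET_BOOLS = ((True, True), (True, False), (False, True), (False, False))

#: IL-12/CD86/IDO combinations, in fixed sampling order.
FUNC_COMBOS = tuple(itertools.product([True, False], repeat=3))
FUNC_COMBO_NAMES = tuple(
    "IL-12%sCD86%sIDO%s" % tuple("+" if b else "-" for b in combo) for combo in FUNC_COMBOS
)


class MixtureValidationError(ValueError):
    """Raised when a phenotype-mixture probability block is invalid."""


def _default_mfi_modes() -> dict[str, tuple[float, float, float]]:
    # (low-mode median, high-mode median, log-sd); ~10x separation between
    # negative and positive cells, typical of a clean membrane stain.
    return {m: (25.0, 250.0, 0.35) for m in ALL_MARKERS}


def _default_p_func() -> dict[str, tuple[float, ...]]:
    # Activator-leaning combinations (IL-12+/CD86+) dominate CD40+ subsets;
    # CD40- subsets carry more IDO single positives.  Order: FUNC_COMBOS.
    activator = (0.05, 0.40, 0.02, 0.08, 0.03, 0.17, 0.10, 0.15)
    mixed = (0.03, 0.30, 0.02, 0.07, 0.05, 0.15, 0.23, 0.15)
    return {
        "CD40+PD-L1+": activator,
        "CD40+PD-L1-": activator,
        "CD40-PD-L1+": mixed,
        "CD40-PD-L1-": mixed,
    }


@dataclass(frozen=True)
class PhenotypeMixture:
    """Hierarchical per-cell phenotype law for one simulated field.

    The default parameterisation resembles a disease-free melanoma field:
    ~17% of nucleated cells are cDC1s, with the CD40-PD-L1+ subset the
    largest of the four checkpoint subsets.
    """

    frac_cdc1: float = 0.17
    p_cd40_pdl1: tuple[float, float, float, float] = (0.20, 0.25, 0.325, 0.225)
    p_func: dict[str, tuple[float, ...]] = field(default_factory=_default_p_func)
    mfi_modes: dict[str, tuple[float, float, float]] = field(default_factory=_default_mfi_modes)
    background_level: float = 8.0
    noise_sigma: float = 3.0
    #: Chance that a non-cDC1 cell expresses each identity marker alone
    #: (other myeloid / MHC-II+ cells); keeps the triple-positive gate
    #: non-trivial without materially contaminating it.
    p_identity_offtarget: dict[str, float] = field(
        default_factory=lambda: {"CD11c": 0.15, "HLA-DR": 0.20, "BDCA-3": 0.03}
    )

    def validate(self) -> None:
        if not 0.0 <= self.frac_cdc1 <= 1.0:
            raise MixtureValidationError(f"frac_cdc1 must be in [0,1], got {self.frac_cdc1}")
        _check_block("p_cd40_pdl1", self.p_cd40_pdl1, 4)
        for subset in CHECKPOINT_SUBSETS:
            if subset not in self.p_func:
                raise MixtureValidationError(f"p_func missing subset {subset!r}")
            _check_block(f"p_func[{subset!r}]", self.p_func[subset], len(FUNC_COMBOS))
        for marker in ALL_MARKERS:
            if marker not in self.mfi_modes:
                raise MixtureValidationError(f"mfi_modes missing marker {marker!r}")
            low, high, sigma = self.mfi_modes[marker]
            if not (0 < low < high):
                raise MixtureValidationError(
                    f"mfi_modes[{marker!r}]: need 0 < low ({low}) < high ({high})"
                )
            if sigma <= 0:
                raise MixtureValidationError(f"mfi_modes[{marker!r}]: sigma must be > 0")
        if self.noise_sigma < 0 or self.background_level < 0:
            raise MixtureValidationError("background_level and noise_sigma must be >= 0")
        for marker, p in self.p_identity_offtarget.items():
            if not 0.0 <= p <= 1.0:
                raise MixtureValidationError(f"p_identity_offtarget[{marker!r}] not in [0,1]")

    @classmethod
    def disease_free(cls) -> "PhenotypeMixture":
        return cls()

    @classmethod
    def metastatic(cls) -> "PhenotypeMixture":
        """A metastatic-like field: fewer cDC1s, tolerogenic functional bias."""
        tolerogenic = (0.02, 0.08, 0.03, 0.07, 0.05, 0.10, 0.45, 0.20)
        return cls(
            frac_cdc1=0.06,
            p_cd40_pdl1=(0.10, 0.20, 0.167, 0.533),
            p_func={s: tolerogenic for s in CHECKPOINT_SUBSETS},
        )


def _check_block(name: str, probs: Sequence[float], n: int) -> None:
    arr = np.asarray(probs, dtype=float)
    if arr.shape != (n,):
        raise MixtureValidationError(f"{name} must have {n} entries, got shape {arr.shape}")
    if (arr < 0).any() or (arr > 1).any():
        raise MixtureValidationError(f"{name} has entries outside [0,1]")
    if abs(arr.sum() - 1.0) > 1e-9:
        raise MixtureValidationError(f"{name} sums to {arr.sum():.12f}, expected 1")


@dataclass(frozen=True)
class SceneGeometry:
    """Field geometry and optics of the simulated microscope."""

    shape: tuple[int, int] = (1024, 1024)
    radius_mean: float = 7.0
    radius_sd: float = 1.5
    radius_min: float = 3.5
    radius_max: float = 11.0
    #: Minimum center distance as a fraction of the sum of radii; < 1 allows
    #: touching/overlapping pairs (later placement wins contested pixels).
    min_center_factor: float = 0.8
    ring_width: int = 2
    nuclear_amplitude: float = 180.0
    max_tries: int = 500

    def validate(self) -> None:
        if min(self.shape) <= 0:
            raise ValueError(f"field dimensions must be positive, got {self.shape}")
        if not (0 < self.radius_min <= self.radius_mean <= self.radius_max):
            raise ValueError("need 0 < radius_min <= radius_mean <= radius_max")
        if self.ring_width < 0:
            raise ValueError("ring_width must be >= 0")


@dataclass
class SceneTruth:
    """Ground truth attached to one simulated field."""

    labels: np.ndarray
    table: pd.DataFrame
    geometry: SceneGeometry
    mixture: PhenotypeMixture | None
    seed: int
    round_transform: RigidTransform | None = None
    clean_channels: dict[str, np.ndarray] | None = None


class PlacementError(RuntimeError):
    """Raised when the field cannot fit the requested number of nuclei."""

    def __init__(self, placed: int, requested: int):
        self.placed = placed
        self.requested = requested
        super().__init__(f"could only place {placed} of {requested} nuclei; enlarge the field")


def sample_phenotype_table(
    n_cells: int, mixture: PhenotypeMixture, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Draw per-cell phenotypes and true marker amplitudes.

    Returns one row per cell with columns ``cell_id`` (1..n), ``is_cdc1``,
    ``subset`` (CD40/PD-L1 subset name, empty for non-cDC1), one boolean
    column per marker, and ``amp_<marker>`` true amplitudes drawn from the
    log-normal mode matching each boolean.
    """
    mixture.validate()
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    is_cdc1 = rng.random(n_cells) < mixture.frac_cdc1
    subset_idx = rng.choice(4, size=n_cells, p=np.asarray(mixture.p_cd40_pdl1, dtype=float))
    func_draw = np.empty(n_cells, dtype=int)
    for si, subset in enumerate(CHECKPOINT_SUBSETS):
        sel = subset_idx == si
        func_draw[sel] = rng.choice(
            len(FUNC_COMBOS), size=int(sel.sum()), p=np.asarray(mixture.p_func[subset], dtype=float)
        )

    calls: dict[str, np.ndarray] = {}
    for marker in IDENTITY_MARKERS:
        off = rng.random(n_cells) < mixture.p_identity_offtarget.get(marker, 0.0)
        calls[marker] = np.where(is_cdc1, True, off)
    subset_bools = np.asarray(_SUBSET_BOOLS, dtype=bool)[subset_idx].reshape(n_cells, 2)
    calls["CD40"] = is_cdc1 & subset_bools[:, 0]
    calls["PD-L1"] = is_cdc1 & subset_bools[:, 1]
    combos = np.asarray(FUNC_COMBOS, dtype=bool)[func_draw].reshape(n_cells, 3)
    for j, marker in enumerate(FUNCTIONAL_MARKERS):
        calls[marker] = is_cdc1 & combos[:, j]

    subset_names = np.where(
        is_cdc1, np.asarray(CHECKPOINT_SUBSETS, dtype=object)[subset_idx], ""
    )

    data: dict[str, np.ndarray] = {
        "cell_id": np.arange(1, n_cells + 1, dtype=np.int64),
        "is_cdc1": is_cdc1,
        "subset": subset_names,
    }
    for marker in ALL_MARKERS:
        data[marker] = calls[marker]
    for marker in ALL_MARKERS:
        low, high, sigma = mixture.mfi_modes[marker]
        mode = np.where(calls[marker], high, low)
        data[f"amp_{marker}"] = np.exp(rng.normal(np.log(mode), sigma))
    return pd.DataFrame(data)


def _place_nuclei(
    n: int, geometry: SceneGeometry, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Sample non-engulfing ellipse centers/radii/orientations by rejection."""
    rows, cols = geometry.shape
    margin = geometry.radius_max
    centers = np.empty((n, 2))  # (row, col)
    radii = np.clip(
        rng.normal(geometry.radius_mean, geometry.radius_sd, size=(n, 2)),
        geometry.radius_min,
        geometry.radius_max,
    )
    orientations = rng.uniform(0, np.pi, size=n)
    mean_r = radii.mean(axis=1)
    for i in range(n):
        for _ in range(geometry.max_tries):
            cand = np.array(
                [rng.uniform(margin, rows - 1 - margin), rng.uniform(margin, cols - 1 - margin)]
            )
            if i == 0:
                centers[0] = cand
                break
            d = np.hypot(*(centers[:i] - cand).T)
            if np.all(d >= geometry.min_center_factor * (mean_r[:i] + mean_r[i])):
                centers[i] = cand
                break
        else:
            raise PlacementError(i, n)
    return centers, radii, orientations, mean_r


def render_scene(
    truth_table: pd.DataFrame,
    geometry: SceneGeometry | None = None,
    seed: int = 0,
    mixture: PhenotypeMixture | None = None,
) -> tuple[MultiplexImage, SceneTruth]:
    """Rasterise a phenotype table into a multiplexed field.

    Nuclei are rendered into the nuclear channel; each marker channel is a
    perinuclear ring (nearest-nucleus rule for contested pixels) scaled by
    the cell's true amplitude.  Background and Gaussian noise come from the
    mixture (or defaults when the table was built externally).
    """
    geometry = geometry or SceneGeometry()
    geometry.validate()
    background = mixture.background_level if mixture is not None else 8.0
    noise_sigma = mixture.noise_sigma if mixture is not None else 3.0

    n = len(truth_table)
    ss = np.random.SeedSequence(seed)
    place_rng, nuc_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    labels = np.zeros(geometry.shape, dtype=np.int32)
    if n > 0:
        centers, radii, orientations, _ = _place_nuclei(n, geometry, place_rng)
        for i, cid in enumerate(truth_table["cell_id"].to_numpy()):
            rr, cc = ellipse(
                centers[i, 0],
                centers[i, 1],
                radii[i, 0],
                radii[i, 1],
                shape=geometry.shape,
                rotation=orientations[i],
            )
            labels[rr, cc] = int(cid)

    ids = truth_table["cell_id"].to_numpy().astype(int)
    if n > 0 and not np.array_equal(np.unique(labels[labels > 0]), np.sort(ids)):
        raise PlacementError(len(np.unique(labels[labels > 0])), n)

    max_id = int(ids.max()) if n else 0
    ring_src = expand_labels(labels, distance=geometry.ring_width)
    rings = np.where(labels == 0, ring_src, 0)

    clean: dict[str, np.ndarray] = {}
    nuc_amp = np.zeros(max_id + 1)
    if n:
        nuc_amp[ids] = np.exp(nuc_rng.normal(np.log(geometry.nuclear_amplitude), 0.2, size=n))
    clean[NUCLEI_CHANNEL] = nuc_amp[labels]
    # Only marker-positive cells deposit specific ring signal; negative
    # cells contribute nothing beyond the field's background and noise, so
    # a marker that is off everywhere yields an identically-zero clean
    # channel.  The low amplitude mode in the truth table models measured
    # residual intensity, not deposited stain.
    for marker in ALL_MARKERS:
        amp = np.zeros(max_id + 1)
        if n:
            amp[ids] = np.where(
                truth_table[marker].to_numpy(dtype=bool),
                truth_table[f"amp_{marker}"].to_numpy(),
                0.0,
            )
        clean[marker] = amp[rings]

    channels = {
        name: np.clip(
            ch + background + noise_rng.normal(0.0, noise_sigma, size=geometry.shape)
            if noise_sigma > 0
            else ch + background,
            0,
            None,
        )
        for name, ch in clean.items()
    }

    table = truth_table.copy()
    if n:
        com = ndimage.center_of_mass(np.ones_like(labels), labels, ids)
        com = np.asarray(com, dtype=float)
        table["centroid_row"] = com[:, 0]
        table["centroid_col"] = com[:, 1]
    else:
        table["centroid_row"] = pd.Series(dtype=float)
        table["centroid_col"] = pd.Series(dtype=float)

    image = MultiplexImage(channels, round_id=1, metadata={"seed": seed})
    truth = SceneTruth(
        labels=labels,
        table=table,
        geometry=geometry,
        mixture=mixture,
        seed=seed,
        clean_channels=clean,
    )
    return image, truth


def simulate_field(
    n_cells: int,
    mixture: PhenotypeMixture | None = None,
    geometry: SceneGeometry | None = None,
    seed: int = 0,
) -> tuple[MultiplexImage, SceneTruth]:
    """Sample a phenotype table and render it: one call per field."""
    mixture = mixture or PhenotypeMixture()
    ss = np.random.SeedSequence(seed)
    table_seed, render_seed = ss.spawn(2)
    table = sample_phenotype_table(n_cells, mixture, np.random.default_rng(table_seed))
    image, truth = render_scene(
        table, geometry=geometry, seed=int(render_seed.generate_state(1)[0] % (2**31)), mixture=mixture
    )
    truth.seed = seed
    image.metadata["seed"] = seed
    return image, truth


def make_second_round(
    scene: SceneTruth,
    image: MultiplexImage,
    transform: RigidTransform,
    round2_channels: Sequence[str] = ROUND2_MARKERS,
    noise_seed: int = 0,
) -> MultiplexImage:
    """Derive a displaced second staining round from a rendered scene.

    The second-round stack (nuclei + the requested markers) is the clean
    scene resampled under ``transform`` with fresh background noise, as if
    the field had been re-localised imperfectly on the second imaging day.
    The transform is recorded on the scene truth.
    """
    if scene.clean_channels is None or NUCLEI_CHANNEL not in scene.clean_channels:
        raise ValueError("scene has no clean nuclei channel to displace")
    background = scene.mixture.background_level if scene.mixture is not None else 8.0
    noise_sigma = scene.mixture.noise_sigma if scene.mixture is not None else 3.0

    names = [NUCLEI_CHANNEL, *round2_channels]
    rng = np.random.default_rng(noise_seed)
    channels: dict[str, np.ndarray] = {}
    validity = None
    for name in names:
        warped, validity = apply_transform(scene.clean_channels[name], transform)
        noisy = warped + background + rng.normal(0.0, noise_sigma, size=warped.shape)
        channels[name] = np.clip(noisy, 0, None)
    if validity is not None and not validity.any():
        raise ValueError("transform displaces the field entirely out of view")
    scene.round_transform = transform
    return MultiplexImage(channels, round_id=2, metadata={"true_transform": transform})


def split_dataset(
    items: Sequence, proportions: Sequence[float | int], seed: int = 0
) -> tuple[list, list, list]:
    """Randomly partition ``items`` into train/validation/test lists.

    ``proportions`` is either three integer counts summing to ``len(items)``
    or three ratios summing to 1 (converted to counts by largest remainder).
    """
    if len(proportions) != 3:
        raise ValueError("proportions must have exactly 3 entries (train, val, test)")
    n = len(items)
    props = list(proportions)
    if all(float(p).is_integer() for p in props) and sum(props) == n:
        counts = [int(p) for p in props]
    elif abs(sum(float(p) for p in props) - 1.0) < 1e-9:
        raw = [float(p) * n for p in props]
        counts = [int(np.floor(r)) for r in raw]
        rem = n - sum(counts)
        order = np.argsort([-(r - np.floor(r)) for r in raw])
        for i in range(rem):
            counts[order[i]] += 1
    else:
        raise ValueError(
            f"proportions {proportions} are neither counts summing to {n} nor ratios summing to 1"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    bounds = np.cumsum(counts)
    idx = [perm[: bounds[0]], perm[bounds[0] : bounds[1]], perm[bounds[1] : bounds[2]]]
    return tuple([items[i] for i in part] for part in idx)  # type: ignore[return-value]


def _apply_augment(
    image: np.ndarray,
    mask: np.ndarray,
    k90: int,
    flip_rows: bool,
    flip_cols: bool,
    intensity_scale: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One augmentation draw: joint geometry on image+mask, jitter on image only."""

    def geom(a: np.ndarray) -> np.ndarray:
        out = np.rot90(a, k=k90)
        if flip_rows:
            out = out[::-1, :]
        if flip_cols:
            out = out[:, ::-1]
        return np.ascontiguousarray(out)

    return geom(np.asarray(image, dtype=float)) * intensity_scale, geom(mask)


def augment_dataset(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    factor: int,
    seed: int = 0,
    intensity_range: tuple[float, float] = (0.7, 1.3),
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Expand (image, mask) pairs ``factor``-fold by random rigid flips.

    Geometry draws are axis-preserving (90-degree rotations plus axis
    flips), applied jointly to image and mask so label rasters stay exact
    integer masks; a multiplicative intensity jitter is applied to the image
    only.  ``factor=0`` means no augmentation and returns the original pairs
    unchanged; ``factor=k`` returns ``k * len(pairs)`` pairs.
    """
    if factor < 0:
        raise ValueError("factor must be >= 0")
    if factor == 0:
        return list(pairs)
    rng = np.random.default_rng(seed)
    out: list[tuple[np.ndarray, np.ndarray]] = []
    for image, mask in pairs:
        for _ in range(factor):
            k90 = int(rng.integers(0, 4))
            flip_r = bool(rng.integers(0, 2))
            flip_c = bool(rng.integers(0, 2))
            scale = float(rng.uniform(*intensity_range))
            out.append(_apply_augment(image, mask, k90, flip_r, flip_c, scale))
    return out
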