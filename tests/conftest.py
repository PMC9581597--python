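"""Shared fixtures: one small rendered scene reused across test modules."""

import numpy as np
import pytest

from mifquant.markers import extract_features
from mifquant.synthetic import PhenotypeMixture, SceneGeometry, simulate_field

#: Midpoint of the default low/high log-normal amplitude modes (geometric
#: mean of 25 and 250) — the natural fixed intensity threshold.
MODE_MIDPOINT = float(np.sqrt(25.0 * 250.0))

SMALL_SHAPE = (360, 360)


@pytest.fixture(scope="session")
def small_scene():
    """A 250-cell disease-free-like field with ground truth."""
    image, truth = simulate_field(
        250, PhenotypeMixture(), SceneGeometry(shape=SMALL_SHAPE), seed=11
    )
    return image, truth


@pytest.fixture(scope="session")
def small_features(small_scene):
    """Features of the small scene against its true labels, midpoint reference."""
    image, truth = small_scene
    return extract_features(image, truth.labels, ring_width=3, ref_intensity=MODE_MIDPOINT)
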