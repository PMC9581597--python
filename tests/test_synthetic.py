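"""Generator correctness: mixture sampling, rendering, splits, augmentation."""

import numpy as np
import pandas as pd
import pytest

from mifquant.image import ALL_MARKERS, IDENTITY_MARKERS, NUCLEI_CHANNEL
from mifquant.registration import RigidTransform
from mifquant.synthetic import (
    CHECKPOINT_SUBSETS,
    MixtureValidationError,
    PhenotypeMixture,
    PlacementError,
    SceneGeometry,
    _apply_augment,
    augment_dataset,
    make_second_round,
    render_scene,
    sample_phenotype_table,
    simulate_field,
    split_dataset,
)


def quiet_mixture(**kw) -> PhenotypeMixture:
    """A noiseless, background-free mixture with no off-target identity."""
    return PhenotypeMixture(
        background_level=0.0,
        noise_sigma=0.0,
        p_identity_offtarget={m: 0.0 for m in IDENTITY_MARKERS},
        **kw,
    )


class TestPhenotypeTable:
    def test_empty_table(self):
        table = sample_phenotype_table(0, PhenotypeMixture(), seed=0)
        assert len(table) == 0
        assert set(ALL_MARKERS) <= set(table.columns)

    def test_degenerate_mixture_all_one_subset(self):
        mix = PhenotypeMixture(frac_cdc1=1.0, p_cd40_pdl1=(0.0, 1.0, 0.0, 0.0))
        table = sample_phenotype_table(200, mix, seed=1)
        for m in IDENTITY_MARKERS:
            assert table[m].all()
        assert table["CD40"].all()
        assert not table["PD-L1"].any()
        assert (table["subset"] == "CD40+PD-L1-").all()

    def test_cdc1_fraction_within_binomial_error(self):
        n = 10_000
        p = 0.17
        table = sample_phenotype_table(n, PhenotypeMixture(frac_cdc1=p), seed=7)
        sd = np.sqrt(p * (1 - p) / n)
        assert abs(table["is_cdc1"].mean() - p) < 3 * sd

    def test_amplitudes_track_calls(self):
        mix = PhenotypeMixture()
        table = sample_phenotype_table(4000, mix, seed=3)
        low, high, _ = mix.mfi_modes["CD40"]
        pos = table.loc[table["CD40"], "amp_CD40"]
        neg = table.loc[~table["CD40"], "amp_CD40"]
        assert np.median(pos) > np.sqrt(low * high) > np.median(neg)

    @pytest.mark.parametrize(
        "kwargs, fragment",
        [
            (dict(frac_cdc1=1.5), "frac_cdc1"),
            (dict(p_cd40_pdl1=(0.5, 0.5, 0.2, 0.0)), "p_cd40_pdl1"),
            (dict(p_func={s: (1.0,) * 8 for s in CHECKPOINT_SUBSETS}), "p_func"),
            (dict(mfi_modes={m: (250.0, 25.0, 0.35) for m in ALL_MARKERS}), "mfi_modes"),
        ],
    )
    def test_invalid_blocks_rejected_by_name(self, kwargs, fragment):
        with pytest.raises(MixtureValidationError, match=fragment):
            sample_phenotype_table(5, PhenotypeMixture(**kwargs), seed=0)


class TestRenderScene:
    def test_marker_off_channel_is_zero(self):
        mix = quiet_mixture(frac_cdc1=0.0)
        table = sample_phenotype_table(1, mix, seed=0)
        image, _ = render_scene(table, SceneGeometry(shape=(96, 96)), seed=0, mixture=mix)
        for m in ALL_MARKERS:
            assert not image[m].any()
        assert image[NUCLEI_CHANNEL].any()

    def test_label_count_matches_rows(self):
        table = sample_phenotype_table(50, PhenotypeMixture(), seed=2)
        image, truth = render_scene(table, SceneGeometry(shape=(300, 300)), seed=2)
        ids = np.unique(truth.labels)
        assert len(ids[ids > 0]) == 50
        assert set(ids[ids > 0]) == set(truth.table["cell_id"])

    def test_same_seed_bit_identical(self):
        a_img, a_truth = simulate_field(60, seed=9)
        b_img, b_truth = simulate_field(60, seed=9)
        for name in a_img.names:
            np.testing.assert_array_equal(a_img[name], b_img[name])
        np.testing.assert_array_equal(a_truth.labels, b_truth.labels)
        pd.testing.assert_frame_equal(a_truth.table, b_truth.table)

    def test_field_too_small_raises_placement_error(self):
        table = sample_phenotype_table(500, PhenotypeMixture(), seed=0)
        with pytest.raises(PlacementError, match="place"):
            render_scene(table, SceneGeometry(shape=(80, 80)), seed=0)

    def test_channel_names(self, small_scene):
        image, _ = small_scene
        assert image.names == (NUCLEI_CHANNEL, *ALL_MARKERS)


class TestSecondRound:
    def test_identity_zero_noise_reproduces_nuclei(self):
        mix = quiet_mixture()
        image, truth = simulate_field(40, mix, SceneGeometry(shape=(240, 240)), seed=4)
        r2 = make_second_round(truth, image, RigidTransform(), noise_seed=1)
        np.testing.assert_allclose(r2[NUCLEI_CHANNEL], image[NUCLEI_CHANNEL], atol=1e-9)

    def test_translation_moves_every_nucleus(self):
        mix = quiet_mixture()
        image, truth = simulate_field(40, mix, SceneGeometry(shape=(240, 240)), seed=5)
        t = RigidTransform(0.0, (5.0, -3.0))
        r2 = make_second_round(truth, image, t, noise_seed=1)
        # out(p) = in(p - t): the content shifts by (dx, dy) = (5, -3).
        moved = r2[NUCLEI_CHANNEL]
        orig = image[NUCLEI_CHANNEL]
        np.testing.assert_allclose(moved[20:-20, 20:-20], orig[23:-17, 15:-25], atol=1e-6)

    def test_transform_recorded_on_truth(self):
        image, truth = simulate_field(30, seed=6, geometry=SceneGeometry(shape=(240, 240)))
        t = RigidTransform(1.0, (2.0, 2.0), center=(119.5, 119.5))
        make_second_round(truth, image, t, noise_seed=0)
        assert truth.round_transform == t

    def test_fully_out_of_view_rejected(self):
        image, truth = simulate_field(10, seed=6, geometry=SceneGeometry(shape=(200, 200)))
        with pytest.raises(ValueError, match="out of view"):
            make_second_round(truth, image, RigidTransform(0.0, (500.0, 500.0)), noise_seed=0)


class TestSplitDataset:
    def test_paper_style_8_2_2_split(self):
        items = [f"img{i}" for i in range(12)]
        train, val, test = split_dataset(items, (8, 2, 2), seed=0)
        assert (len(train), len(val), len(test)) == (8, 2, 2)
        assert sorted(train + val + test) == sorted(items)
        assert not (set(train) & set(val) | set(train) & set(test) | set(val) & set(test))

    def test_all_in_training(self):
        train, val, test = split_dataset([1, 2, 3], (3, 0, 0), seed=1)
        assert sorted(train) == [1, 2, 3] and not val and not test

    def test_ratio_proportions(self):
        train, val, test = split_dataset(list(range(10)), (0.8, 0.1, 0.1), seed=0)
        assert (len(train), len(val), len(test)) == (8, 1, 1)

    def test_bad_counts_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([1, 2, 3], (2, 2, 2), seed=0)

    def test_seed_changes_permutation_not_sizes(self):
        items = list(range(12))
        a = split_dataset(items, (8, 2, 2), seed=1)
        b = split_dataset(items, (8, 2, 2), seed=2)
        assert [len(x) for x in a] == [len(x) for x in b] == [8, 2, 2]
        assert a != b
        assert a == split_dataset(items, (8, 2, 2), seed=1)


class TestAugmentation:
    @staticmethod
    def _pairs(n, rng):
        return [
            (rng.random((20, 20)), rng.integers(0, 4, size=(20, 20)).astype(np.int32))
            for _ in range(n)
        ]

    def test_factor_five_grows_8_to_40(self):
        rng = np.random.default_rng(0)
        out = augment_dataset(self._pairs(8, rng), factor=5, seed=0)
        assert len(out) == 40

    def test_factor_zero_returns_originals(self):
        rng = np.random.default_rng(0)
        pairs = self._pairs(3, rng)
        out = augment_dataset(pairs, factor=0, seed=0)
        assert len(out) == 3
        for (ai, am), (bi, bm) in zip(pairs, out):
            assert ai is bi and am is bm

    def test_identity_draw_equals_input(self):
        rng = np.random.default_rng(1)
        image, mask = self._pairs(1, rng)[0]
        out_img, out_mask = _apply_augment(image, mask, k90=0, flip_rows=False,
                                           flip_cols=False, intensity_scale=1.0)
        np.testing.assert_array_equal(out_img, image)
        np.testing.assert_array_equal(out_mask, mask)

    def test_label_sets_preserved_over_100_draws(self):
        rng = np.random.default_rng(2)
        mask = np.zeros((16, 16), dtype=np.int32)
        mask[2:6, 2:6] = 3
        mask[9:14, 8:15] = 7
        pairs = [(rng.random((16, 16)), mask)]
        out = augment_dataset(pairs, factor=100, seed=3)
        for _, m in out:
            assert set(np.unique(m)) == {0, 3, 7}
            assert np.issubdtype(m.dtype, np.integer)

    def test_geometry_applied_jointly(self):
        image = np.zeros((10, 10))
        image[1, 2] = 5.0
        mask = np.zeros((10, 10), dtype=np.int32)
        mask[1, 2] = 1
        for k in range(4):
            for fr in (False, True):
                for fc in (False, True):
                    oi, om = _apply_augment(image, mask, k, fr, fc, 2.0)
                    assert np.argwhere(oi > 0).tolist() == np.argwhere(om > 0).tolist()
                    assert oi.max() == 10.0  # jitter on image only
                    assert om.max() == 1


class TestSplitProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(n=st.integers(0, 60), seed=st.integers(0, 2**20))
    @settings(derandomize=True, max_examples=60)
    def test_any_count_split_is_a_partition(self, n, seed):
        rng = np.random.default_rng(seed)
        counts = rng.multinomial(n, [1 / 3] * 3)
        parts = split_dataset(list(range(n)), tuple(int(c) for c in counts), seed=seed)
        assert [len(p) for p in parts] == list(counts)
        assert sorted(x for p in parts for x in p) == list(range(n))
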