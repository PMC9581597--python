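"""Feature extraction and marker-positivity classification."""

import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk
from skimage.segmentation import expand_labels
from sklearn.metrics import balanced_accuracy_score, roc_auc_score

from conftest import MODE_MIDPOINT
from mifquant.image import ALL_MARKERS, MultiplexImage
from mifquant.markers import (
    apply_marker_classifier,
    classifier_distance_to_truth,
    classify_by_threshold,
    extract_features,
    refine_classifier,
    train_marker_classifier,
)


def single_cell_image(ring_amplitude: float = 50.0):
    """One disc nucleus; marker signal only on its 3-px ring."""
    labels = np.zeros((40, 40), np.int32)
    labels[disk((20, 20), 7)] = 1
    ring = (expand_labels(labels, 3) == 1) & (labels == 0)
    marker = np.where(ring, ring_amplitude, 0.0)
    nuclei = np.where(labels == 1, 180.0, 0.0)
    image = MultiplexImage({"nuclei": nuclei, "CD40": marker})
    return image, labels, ring


class TestExtractFeatures:
    def test_constructed_ring_and_nucleus_means(self):
        image, labels, ring = single_cell_image(ring_amplitude=50.0)
        feats = extract_features(image, labels, ring_width=3, ref_intensity=25.0)
        row = feats.iloc[0]
        assert row["CD40_ring_mean"] == pytest.approx(50.0)
        assert row["CD40_nuc_mean"] == 0.0
        assert 0 < row["CD40_frac_above"] < 1
        assert row["area"] == (labels == 1).sum()

    def test_zero_channel_all_zero_features(self):
        image, labels, _ = single_cell_image(ring_amplitude=0.0)
        feats = extract_features(image, labels, ring_width=3, ref_intensity=10.0)
        assert feats["CD40_ring_mean"].iloc[0] == 0.0
        assert feats["CD40_frac_above"].iloc[0] == 0.0
        assert not classify_by_threshold(feats, "CD40").iloc[0]

    def test_ring_mean_separates_classes(self, small_scene, small_features):
        _, truth = small_scene
        auc = roc_auc_score(
            truth.table["CD40"].to_numpy(), small_features["CD40_ring_mean"].to_numpy()
        )
        assert auc > 0.95

    def test_shape_mismatch_rejected(self, small_scene):
        image, truth = small_scene
        with pytest.raises(Exception, match="shape"):
            extract_features(image, truth.labels[:-5])


class TestThresholdClassifier:
    def test_midpoint_threshold_recovers_calls(self, small_scene, small_features):
        _, truth = small_scene
        for marker in ALL_MARKERS:
            calls = classify_by_threshold(small_features, marker)
            agreement = (calls.to_numpy() == truth.table[marker].to_numpy()).mean()
            assert agreement >= 0.95, marker

    def test_all_pixels_above_any_fraction_positive(self):
        image, labels, _ = single_cell_image(ring_amplitude=100.0)
        # Reference below every cell pixel: nucleus pixels are 0 on the
        # marker channel, so only a sub-1 fraction is attainable there.
        feats = extract_features(image, labels, ring_width=0, ref_intensity=0.5)
        # ring_width=0: cell support is the nucleus only -> fraction is 0.
        assert feats["CD40_frac_above"].iloc[0] == 0.0

    def test_raising_threshold_never_flips_negative_to_positive(self, small_scene):
        image, truth = small_scene
        low = extract_features(image, truth.labels, ring_width=3, ref_intensity=40.0)
        high = extract_features(image, truth.labels, ring_width=3, ref_intensity=120.0)
        for marker in ("CD40", "CD11c"):
            calls_low = classify_by_threshold(low, marker)
            calls_high = classify_by_threshold(high, marker)
            assert not (calls_high & ~calls_low).any()

    def test_mismatched_reference_is_an_error(self, small_features):
        with pytest.raises(ValueError, match="re-run extract_features"):
            classify_by_threshold(small_features, "CD40", intensity_threshold=123.0)

    def test_unknown_marker_rejected(self, small_features):
        with pytest.raises(KeyError):
            classify_by_threshold(small_features, "CD99")


class TestFewShot:
    @staticmethod
    def _exemplars(truth_table, marker, n, seed):
        rng = np.random.default_rng(seed)
        pos = truth_table.loc[truth_table[marker], "cell_id"].to_numpy()
        neg = truth_table.loc[~truth_table[marker].astype(bool), "cell_id"].to_numpy()
        k = min(n, len(pos), len(neg))
        return (
            [int(i) for i in rng.choice(pos, k, replace=False)],
            [int(i) for i in rng.choice(neg, k, replace=False)],
        )

    def test_separable_exemplars_perfect_training_accuracy(self, small_scene, small_features):
        _, truth = small_scene
        pos, neg = self._exemplars(truth.table, "CD40", 10, seed=0)
        clf = train_marker_classifier(small_features, pos, neg, "CD40")
        calls, _ = apply_marker_classifier(clf, small_features)
        by_id = calls.set_axis(small_features["cell_id"])
        assert by_id.loc[pos].all()
        assert not by_id.loc[neg].any()

    def test_held_out_balanced_accuracy(self, small_scene, small_features):
        _, truth = small_scene
        pos, neg = self._exemplars(truth.table, "PD-L1", 10, seed=1)
        clf = train_marker_classifier(small_features, pos, neg, "PD-L1")
        calls, probs = apply_marker_classifier(clf, small_features)
        held_out = ~small_features["cell_id"].isin(pos + neg)
        score = balanced_accuracy_score(
            truth.table.loc[held_out.to_numpy(), "PD-L1"], calls[held_out]
        )
        assert score >= 0.95
        assert ((probs >= 0) & (probs <= 1)).all()

    def test_identical_inputs_identical_coefficients(self, small_features, small_scene):
        _, truth = small_scene
        pos, neg = self._exemplars(truth.table, "CD86", 8, seed=2)
        a = train_marker_classifier(small_features, pos, neg, "CD86")
        b = train_marker_classifier(small_features, pos, neg, "CD86")
        np.testing.assert_array_equal(a.coef, b.coef)
        assert a.intercept == b.intercept

    def test_single_class_and_overlap_rejected(self, small_features):
        ids = small_features["cell_id"].tolist()
        with pytest.raises(ValueError, match="both classes"):
            train_marker_classifier(small_features, ids[:5], [], "CD40")
        with pytest.raises(ValueError, match="both classes"):
            train_marker_classifier(small_features, [], ids[:5], "CD40")
        with pytest.raises(ValueError, match="both"):
            train_marker_classifier(small_features, ids[:5], ids[4:8], "CD40")

    def test_unknown_exemplar_id_rejected(self, small_features):
        with pytest.raises(KeyError, match="exemplar"):
            train_marker_classifier(small_features, [999_999], [1], "CD40")

    def test_refinement_does_not_degrade(self, small_scene, small_features):
        _, truth = small_scene
        truth_by_id = truth.table.set_index("cell_id")
        scores_before, scores_after = [], []
        for seed in range(5):
            pos, neg = self._exemplars(truth.table, "IL-12", 6, seed=seed)
            clf = train_marker_classifier(small_features, pos, neg, "IL-12")
            calls, _ = apply_marker_classifier(clf, small_features)
            ids = small_features["cell_id"].to_numpy()
            held = ~np.isin(ids, pos + neg)
            before = balanced_accuracy_score(
                truth_by_id.loc[ids[held], "IL-12"], calls.to_numpy()[held]
            )
            # The analyst corrects five random cells to their true class.
            rng = np.random.default_rng(100 + seed)
            corrected = rng.choice(ids[held], 5, replace=False)
            refined = refine_classifier(
                clf,
                small_features,
                {int(c): bool(truth_by_id.loc[c, "IL-12"]) for c in corrected},
            )
            calls2, _ = apply_marker_classifier(refined, small_features)
            held2 = ~np.isin(ids, list(refined.positive_ids) + list(refined.negative_ids))
            after = balanced_accuracy_score(
                truth_by_id.loc[ids[held2], "IL-12"], calls2.to_numpy()[held2]
            )
            scores_before.append(before)
            scores_after.append(after)
        assert np.mean(scores_after) >= np.mean(scores_before) - 0.01

    def test_calls_invariant_under_relabeling(self, small_scene):
        image, truth = small_scene
        shifted = np.where(truth.labels > 0, truth.labels + 1000, 0)
        a = extract_features(image, truth.labels, ring_width=3, ref_intensity=MODE_MIDPOINT)
        b = extract_features(image, shifted, ring_width=3, ref_intensity=MODE_MIDPOINT)
        np.testing.assert_array_equal(
            classify_by_threshold(a, "CD40").to_numpy(),
            classify_by_threshold(b, "CD40").to_numpy(),
        )


class TestDistanceToTruth:
    def test_equal_calls_zero_distance(self):
        calls = np.array([True, False, True])
        assert classifier_distance_to_truth(calls, calls, 3) == 0.0

    def test_three_point_gap(self):
        truth = np.zeros(100, bool)
        truth[:17] = True
        pred = np.zeros(100, bool)
        pred[:20] = True
        assert classifier_distance_to_truth(pred, truth, 100) == pytest.approx(3.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            classifier_distance_to_truth(np.array([True]), np.array([True]), 0)
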