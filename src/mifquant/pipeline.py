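"""End-to-end pipeline: simulate/register/segment/classify/gate/report."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .image import ALL_MARKERS, NUCLEI_CHANNEL, label_ids
from .io import PipelineConfig, export_cell_table, write_labels, write_multiplex
from .markers import (
    apply_marker_classifier,
    extract_features,
    train_marker_classifier,
)
from .phenotyping import (
    default_cdc1_schema,
    gate_cells,
    population_abundance,
    subset_fractions,
)
from .registration import RigidTransform, align_rounds
from .seg_eval import evaluate_curve
from .segmentation import import_external_labels, segment_nuclei_baseline
from .synthetic import PhenotypeMixture, SceneGeometry, make_second_round, simulate_field


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def draw_exemplars(
    truth_table: pd.DataFrame, marker: str, n_per_class: int, rng: np.random.Generator
) -> tuple[list[int], list[int]]:
    """Sample positive/negative exemplar cell ids from a scene's ground truth.

    Stands in for the interactive step in which an analyst clicks a few
    clearly positive and negative nuclei.  ``n_per_class`` is a target;
    rare markers in small fields yield as many exemplars as exist (at
    least one per class is required).
    """
    pos_pool = truth_table.loc[truth_table[marker], "cell_id"].to_numpy()
    neg_pool = truth_table.loc[~truth_table[marker].astype(bool), "cell_id"].to_numpy()
    if len(pos_pool) == 0 or len(neg_pool) == 0:
        raise ValueError(
            f"cannot draw exemplars for {marker!r}: "
            f"{len(pos_pool)} positive and {len(neg_pool)} negative cells in the field"
        )
    pos = rng.choice(pos_pool, size=min(n_per_class, len(pos_pool)), replace=False)
    neg = rng.choice(neg_pool, size=min(n_per_class, len(neg_pool)), replace=False)
    return [int(i) for i in pos], [int(i) for i in neg]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict[str, object]:
    """Run the full synthetic workflow and write the report bundle.

    Stages: simulate a two-round field → register the rounds → segment
    nuclei (baseline watershed, imported mask, or ground truth) → benchmark
    the segmentation against the scene truth → extract features → few-shot
    classify each marker → gate phenotypes → write cell table, metric
    tables, and a run log.  Deterministic for a fixed config.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    outputs: dict[str, object] = {}

    try:
        mixture = (
            PhenotypeMixture.metastatic()
            if config.mixture == "metastatic"
            else PhenotypeMixture.disease_free()
        )
        geometry = SceneGeometry(shape=config.field_shape)
        image, truth = simulate_field(config.n_cells, mixture, geometry, seed=config.seed)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate", e) from e

    try:
        if config.two_rounds:
            transform = RigidTransform(
                config.round_rotation_deg,
                tuple(config.round_shift),
                center=((config.field_shape[1] - 1) / 2, (config.field_shape[0] - 1) / 2),
            )
            round2 = make_second_round(truth, image, transform, noise_seed=config.seed + 1)
            round1 = image.subset(
                [NUCLEI_CHANNEL] + [m for m in ALL_MARKERS if m not in round2.names]
            )
            merged = align_rounds(round1, round2)
        else:
            merged = image
    except Exception as e:  # noqa: BLE001
        raise PipelineError("register", e) from e

    try:
        if config.segmentation == "baseline":
            labels = segment_nuclei_baseline(merged[NUCLEI_CHANNEL])
        elif config.segmentation == "import":
            if not config.external_mask:
                raise ValueError("segmentation='import' requires external_mask")
            labels = import_external_labels(config.external_mask, merged)
        else:
            labels = truth.labels
    except Exception as e:  # noqa: BLE001
        raise PipelineError("segment", e) from e

    try:
        seg_metrics = evaluate_curve(
            truth.labels, labels, config.iou_thresholds, policy=config.match_policy
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("benchmark-seg", e) from e

    try:
        features = extract_features(merged, labels, ring_width=config.ring_width)
        cell_table = features.copy()
        # Few-shot classification per marker, exemplars drawn from truth via
        # nearest-centroid correspondence between truth cells and instances.
        truth_by_instance = _match_truth_to_instances(truth.table, features)
        for marker in ALL_MARKERS:
            pos, neg = draw_exemplars(
                truth_by_instance, marker, config.n_exemplars, rng
            )
            clf = train_marker_classifier(features, pos, neg, marker)
            calls, probs = apply_marker_classifier(clf, features)
            cell_table[marker] = calls
            cell_table[f"{marker}_prob"] = probs
    except Exception as e:  # noqa: BLE001
        raise PipelineError("classify", e) from e

    try:
        schema = default_cdc1_schema()
        members = gate_cells(cell_table, schema)
        n_total = len(cell_table)
        abundances = pd.DataFrame(
            {
                "population": list(members.columns),
                "count": [int(members[c].sum()) for c in members.columns],
                "pct_of_nucleated": [
                    population_abundance(members[c], n_total) for c in members.columns
                ],
            }
        )
        subset_cols = [f"cDC1/{s}" for s in _checkpoint_subset_names()]
        frac = subset_fractions(members["cDC1"], members[subset_cols])
        subset_table = pd.DataFrame(
            {
                "subset": subset_cols,
                "count": frac.counts.to_numpy(),
                "pct_of_cdc1": frac.fractions_pct.to_numpy(),
            }
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("gate", e) from e

    try:
        write_multiplex(merged, out_dir / "merged.tif")
        write_labels(labels, out_dir / "labels.tif")
        export_cell_table(cell_table, out_dir / "cells.csv")
        export_cell_table(truth.table, out_dir / "truth_cells.csv")
        seg_metrics.to_csv(out_dir / "seg_metrics.csv", index=False)
        abundances.to_csv(out_dir / "populations.csv", index=False)
        subset_table.to_csv(out_dir / "subset_fractions.csv", index=False)
        log = {
            "mifquant_version": __version__,
            "config": yaml.safe_load(config.to_yaml()),
            "n_instances": int(len(label_ids(labels))),
            "n_truth_cells": int(len(truth.table)),
        }
        if config.two_rounds:
            t = merged.metadata["round_transform"]
            log["estimated_round_transform"] = {
                "rotation_deg": float(t.rotation_deg),
                "translation": [float(x) for x in t.translation],
            }
            log["registration_quality"] = float(merged.metadata["registration_quality"])
        (out_dir / "log.yaml").write_text(yaml.safe_dump(log, sort_keys=False))
    except Exception as e:  # noqa: BLE001
        raise PipelineError("report", e) from e

    outputs.update(
        image=merged,
        labels=labels,
        truth=truth,
        cell_table=cell_table,
        seg_metrics=seg_metrics,
        abundances=abundances,
        subset_fractions=subset_table,
        out_dir=out_dir,
    )
    return outputs


def _checkpoint_subset_names() -> list[str]:
    return ["CD40+PD-L1+", "CD40+PD-L1-", "CD40-PD-L1+", "CD40-PD-L1-"]


def _match_truth_to_instances(
    truth_table: pd.DataFrame, features: pd.DataFrame, max_dist: float = 8.0
) -> pd.DataFrame:
    """Relabel truth rows by the nearest segmented instance's cell id.

    Lets exemplars drawn from the scene truth reference instances from an
    imperfect segmentation.  Truth cells with no instance centroid within
    ``max_dist`` pixels are dropped.
    """
    from scipy.spatial import cKDTree

    if features.empty:
        raise ValueError("no segmented instances to match against")
    tree = cKDTree(features[["centroid_row", "centroid_col"]].to_numpy())
    dists, idx = tree.query(truth_table[["centroid_row", "centroid_col"]].to_numpy())
    matched = truth_table.loc[dists <= max_dist].copy()
    matched["cell_id"] = features["cell_id"].to_numpy()[idx[dists <= max_dist]]
    # If two truth cells map to one instance keep the nearer one.
    matched["_dist"] = dists[dists <= max_dist]
    matched = matched.sort_values("_dist").drop_duplicates("cell_id").drop(columns="_dist")
    return matched
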