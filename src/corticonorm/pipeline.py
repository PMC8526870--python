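"""End-to-end orchestration of the normative-modelling analysis.

``run_pipeline`` executes: simulate -> split -> fit-normative ->
deviations -> group statistics (age association, group difference,
group x PMA interaction) -> age prediction -> outcome associations, writing
each stage's TSV/JSON outputs into the run directory and a manifest with
per-file SHA-256 hashes, per-stage wall-clock and the echoed seeds, so every
number in every output is reproducible from the manifest alone.

Each stochastic stage draws its own child seed from the run seed, so stages
can be re-run or toggled without perturbing the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as cio
from .ageprediction import (
    AgePredConfig,
    age_prediction_report_frame,
    evaluate_age_model,
    fit_bias_correction,
    summarize_importance,
    train_age_model,
)
from .associations import index_correlation, index_group_test, z_covariate_map
from .cohort import (
    default_effect_config,
    generate_features,
    generate_parcellation,
    sample_demographics,
)
from .deviations import (
    atypicality_indices,
    classify_extremes,
    compute_z_scores,
    overlap_map,
)
from .normative import evaluate_mae, fit_normative_model, predict, split_cohort
from .permutation import design_age, design_group, interaction_test, permutation_test

logger = logging.getLogger(__name__)

EXIT_CONFIG_ERROR = 2
EXIT_STAGE_FAILURE = 3


@dataclass
class RunConfig:
    """Everything a full run needs; round-trips losslessly through YAML."""

    n_term: int = 60
    n_preterm: int = 20
    parcels_per_hemisphere: int = 30
    seed: int = 0
    holdout_fraction: float = 0.25
    gp_restarts: int = 5
    n_permutations: int = 500
    extreme_threshold: float = 3.1
    alpha: float = 0.05
    run_age_prediction: bool = True
    run_group_stats: bool = True
    run_associations: bool = True
    rf_n_estimators: int = 1000
    effect_overrides: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all enabled stages; returns the manifest (also written to
    ``manifest.json``). Any stage failure raises after writing a partial
    manifest naming the stage."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "stage_seeds": seeds,
        "stages": {},
    }
    config.to_yaml(out / "run_config.yaml")

    stage = "simulate"
    try:
        t0 = time.perf_counter()
        parcels = generate_parcellation(config.parcels_per_hemisphere, seeds[0])
        subjects = sample_demographics(config.n_term, config.n_preterm, seeds[1])
        effect_cfg = default_effect_config(seed=seeds[2], **config.effect_overrides)
        table, truth = generate_features(subjects, parcels, effect_cfg)
        cio.write_subjects(subjects, out / "subjects.tsv")
        cio.write_parcels(parcels, out / "parcels.tsv")
        cio.write_feature_table(table, out / "features.tsv")
        cio.write_ground_truth(truth, table, out / "ground_truth.tsv")
        manifest["stages"][stage] = {"seconds": time.perf_counter() - t0}

        stage = "split"
        t0 = time.perf_counter()
        term = subjects[subjects["group"] == "term"].reset_index(drop=True)
        split = split_cohort(term, config.holdout_fraction, seeds[3])
        split.rename_axis("subject_id").reset_index().to_csv(
            out / "split.tsv", sep="\t", index=False, lineterminator="\n"
        )
        manifest["stages"][stage] = {"seconds": time.perf_counter() - t0}

        stage = "fit-normative"
        t0 = time.perf_counter()
        train_ids = split.index[split == "train"]
        holdout_ids = split.index[split == "holdout"]
        train_table = table.subset(train_ids)
        holdout_table = table.subset(holdout_ids)
        model = fit_normative_model(train_table, restarts=config.gp_restarts,
                                    seed=seeds[4])
        model.save(out / "normative_model.json")
        mae = evaluate_mae(model, holdout_table)
        _write_cell_map(mae, parcels.parcel_ids, table.metrics,
                        out / "holdout_mae.tsv", "mae")
        manifest["stages"][stage] = {"seconds": time.perf_counter() - t0}

        stage = "deviations"
        t0 = time.perf_counter()
        scored_ids = list(holdout_ids) + list(
            subjects.loc[subjects["group"] == "preterm", "subject_id"]
        )
        scored = table.subset(scored_ids)
        pred = predict(model, scored.subjects)
        z = compute_z_scores(pred, scored)
        mask = classify_extremes(z, config.extreme_threshold)
        preterm_ids = subjects.loc[subjects["group"] == "preterm", "subject_id"]
        overlap = overlap_map(mask, preterm_ids)
        indices = atypicality_indices(mask)
        cio.write_z_scores(z, out / "z_scores.tsv")
        cio.write_extreme_mask(mask, out / "extreme_mask.tsv")
        cio.write_overlap_map(overlap, out / "overlap_map.tsv", group="preterm")
        cio.write_atypicality(indices, out / "atypicality.tsv")
        manifest["stages"][stage] = {"seconds": time.perf_counter() - t0}

        if config.run_group_stats:
            stage = "group-stats"
            t0 = time.perf_counter()
            res_age = permutation_test(
                table.subset(term["subject_id"]), design_age(term),
                n_perm=config.n_permutations, seed=seeds[5], alpha=config.alpha,
            )
            cio.write_stat_map(res_age, parcels.parcel_ids, table.metrics,
                               out / "stat_map_age.tsv", "age")
            res_inter = interaction_test(
                table, n_perm=config.n_permutations, seed=seeds[5],
                alpha=config.alpha,
            )
            cio.write_stat_map(res_inter, parcels.parcel_ids, table.metrics,
                               out / "stat_map_interaction.tsv", "interaction")
            res_group = permutation_test(
                table, design_group(subjects), n_perm=config.n_permutations,
                seed=seeds[5], alpha=config.alpha,
            )
            cio.write_stat_map(res_group, parcels.parcel_ids, table.metrics,
                               out / "stat_map_group.tsv", "group")
            manifest["stages"][stage] = {"seconds": time.perf_counter() - t0}

        if config.run_age_prediction:
            stage = "age-predict"
            t0 = time.perf_counter()
            rf_cfg = AgePredConfig(n_estimators=config.rf_n_estimators,
                                   seed=seeds[6])
            rf = train_age_model(train_table, rf_cfg)
            correction = fit_bias_correction(
                rf.predict(train_table.flatten()),
                train_table.subjects["pma_scan"].to_numpy(float),
            )
            report = evaluate_age_model(rf, correction, holdout_table,
                                        train_subject_ids=train_ids)
            age_prediction_report_frame(report).to_csv(
                out / "age_predictions.tsv", sep="\t", index=False,
                lineterminator="\n",
            )
            importance = summarize_importance(rf, table.metrics)
            with open(out / "age_report.json", "w", encoding="utf-8") as fh:
                json.dump(
                    {
                        "mae": report.mae, "mse": report.mse,
                        "spearman_rho": report.spearman_rho,
                        "r_squared": report.r_squared,
                        "importance_counts": importance.counts,
                        "importance_decile_size": importance.decile_size,
                    },
                    fh, indent=2,
                )
            manifest["stages"][stage] = {"seconds": time.perf_counter() - t0}

        if config.run_associations:
            stage = "associations"
            t0 = time.perf_counter()
            ga = scored.subjects["ga_birth"].to_numpy(float)
            res_ga = z_covariate_map(
                z, scored.subjects, "ga_birth", n_perm=config.n_permutations,
                seed=seeds[7], alpha=config.alpha,
            )
            cio.write_stat_map(res_ga, parcels.parcel_ids, table.metrics,
                               out / "stat_map_ga.tsv", "ga-assoc")
            corr = index_correlation(indices, ga, covariate_name="ga_birth")
            corr.to_csv(out / "index_associations.tsv", sep="\t", index=False,
                        lineterminator="\n")
            gtests = index_group_test(
                indices, scored.subjects["group"].to_numpy()
            )
            gtests.to_csv(out / "index_group_tests.tsv", sep="\t", index=False,
                          lineterminator="\n")
            manifest["stages"][stage] = {"seconds": time.perf_counter() - t0}
    except Exception:
        manifest["failed_stage"] = stage
        cio.write_manifest(manifest, out / "manifest.json")
        logger.exception("pipeline stage %r failed", stage)
        raise

    manifest["outputs"] = cio.hash_directory_outputs(out)
    cio.write_manifest(manifest, out / "manifest.json")
    return manifest


def _write_cell_map(values, parcel_ids, metrics, path, value_name) -> None:
    import pandas as pd

    n_p, n_m = values.shape
    frame = pd.DataFrame(
        {
            "parcel_id": np.repeat(parcel_ids, n_m),
            "metric": np.tile(list(metrics), n_p),
            value_name: values.ravel(),
        }
    )
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
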