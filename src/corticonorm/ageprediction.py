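"""Brain-age prediction from parcel-wise cortical features.

A random-forest regressor predicts postmenstrual age at scan from all
(parcel x metric) feature columns. Raw predictions suffer regression to the
mean, so an error-in-variables correction is estimated on the training set
(fit raw = a + b * true, invert as corrected = (raw - a) / b) and applied to
the hold-out sample. Performance is summarised as MAE, MSE, Spearman rho and
R^2 on corrected hold-out predictions; feature importance is summarised as
the per-metric share of the top decile of impurity importances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import r2_score

from .cohort import METRICS, FeatureTable


@dataclass(frozen=True)
class AgePredConfig:
    """Random-forest hyperparameters; the defaults are the tuned optima
    (max_features covers all features at each split, the historical 'auto'
    behaviour for regression forests)."""

    max_depth: int = 35
    max_features: float | int | str = 1.0
    min_samples_leaf: int = 2
    n_estimators: int = 1000
    seed: int = 0


@dataclass(frozen=True)
class BiasCorrection:
    """Training-set regression of raw predictions on true age:
    raw = intercept + slope * true; corrected = (raw - intercept) / slope."""

    intercept: float
    slope: float
    orientation: str = "raw_on_true"

    def apply(self, raw: np.ndarray) -> np.ndarray:
        raw = np.asarray(raw, dtype=float)
        if self.orientation == "raw_on_true":
            return (raw - self.intercept) / self.slope
        return self.intercept + self.slope * raw  # true_on_raw


@dataclass
class PredictionReport:
    mae: float  # weeks
    mse: float  # weeks^2
    spearman_rho: float
    r_squared: float
    true_age: np.ndarray = field(repr=False, default=None)
    raw_pred: np.ndarray = field(repr=False, default=None)
    corrected_pred: np.ndarray = field(repr=False, default=None)
    subject_ids: np.ndarray = field(repr=False, default=None)


@dataclass
class ImportanceSummary:
    """Per-metric membership of the top decile of feature importances."""

    counts: dict[str, int]
    percentages: dict[str, float]
    decile_size: int


def _feature_matrix(table: FeatureTable) -> np.ndarray:
    X = table.flatten()
    if np.isnan(X).any():
        bad_cols = np.flatnonzero(np.isnan(X).any(axis=0))
        n_m = len(table.metrics)
        names = [
            f"parcel {table.parcels.parcel_ids[c // n_m]}/"
            f"{table.metrics[c % n_m]}"
            for c in bad_cols[:10]
        ]
        raise ValueError(f"missing values in feature columns: {names}")
    return X


def train_age_model(
    train_table: FeatureTable, config: AgePredConfig = AgePredConfig()
) -> RandomForestRegressor:
    """Fit the random forest on all flattened features; deterministic given
    the config seed."""
    X = _feature_matrix(train_table)
    y = train_table.subjects["pma_scan"].to_numpy(float)
    model = RandomForestRegressor(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        max_features=config.max_features,
        min_samples_leaf=config.min_samples_leaf,
        random_state=config.seed,
        n_jobs=1,
    )
    model.fit(X, y)
    return model


def fit_bias_correction(
    raw_train_predictions: np.ndarray,
    true_train_ages: np.ndarray,
    orientation: str = "raw_on_true",
) -> BiasCorrection:
    """Least-squares fit of raw predictions on true age (training data only)."""
    raw = np.asarray(raw_train_predictions, dtype=float)
    true = np.asarray(true_train_ages, dtype=float)
    if raw.shape != true.shape or raw.size < 3:
        raise ValueError("need >= 3 matched training predictions")
    if np.ptp(true) == 0:
        raise ValueError("true ages are constant; no age signal to regress on")
    if orientation == "raw_on_true":
        slope, intercept = np.polyfit(true, raw, 1)
    elif orientation == "true_on_raw":
        slope, intercept = np.polyfit(raw, true, 1)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    if abs(slope) < 1e-6:
        raise ValueError("bias-correction slope is ~0; predictions carry no "
                         "age signal")
    return BiasCorrection(intercept=float(intercept), slope=float(slope),
                          orientation=orientation)


def evaluate_age_model(
    model: RandomForestRegressor,
    correction: BiasCorrection,
    holdout_table: FeatureTable,
    train_subject_ids=None,
) -> PredictionReport:
    """MAE / MSE / Spearman rho / R^2 of corrected hold-out predictions."""
    if train_subject_ids is not None:
        overlap = np.intersect1d(
            np.asarray(list(train_subject_ids)), holdout_table.subject_ids
        )
        if overlap.size:
            raise ValueError(
                f"holdout overlaps the training sample: {overlap[:5].tolist()}"
            )
    X = _feature_matrix(holdout_table)
    y = holdout_table.subjects["pma_scan"].to_numpy(float)
    raw = model.predict(X)
    corrected = correction.apply(raw)
    err = corrected - y
    rho = spearmanr(y, corrected).statistic if np.ptp(y) > 0 else float("nan")
    return PredictionReport(
        mae=float(np.abs(err).mean()),
        mse=float((err ** 2).mean()),
        spearman_rho=float(rho),
        r_squared=float(r2_score(y, corrected)),
        true_age=y,
        raw_pred=raw,
        corrected_pred=corrected,
        subject_ids=holdout_table.subject_ids,
    )


def summarize_importance(
    model: RandomForestRegressor,
    metrics: tuple[str, ...] = METRICS,
    top_fraction: float = 0.10,
) -> ImportanceSummary:
    """Per-metric counts within the top ``ceil(top_fraction * n_features)``
    impurity importances (stable feature order breaks ties)."""
    imp = np.asarray(model.feature_importances_)
    n_feat = imp.size
    decile = math.ceil(top_fraction * n_feat)
    top = np.argsort(-imp, kind="stable")[:decile]
    n_m = len(metrics)
    counts = {m: 0 for m in metrics}
    for idx in top:
        counts[metrics[idx % n_m]] += 1
    percentages = {m: 100.0 * c / decile for m, c in counts.items()}
    return ImportanceSummary(counts=counts, percentages=percentages,
                             decile_size=decile)


def age_prediction_report_frame(report: PredictionReport) -> pd.DataFrame:
    """Long per-subject frame of true / raw / corrected ages."""
    return pd.DataFrame(
        {
            "subject_id": report.subject_ids,
            "true_pma": report.true_age,
            "raw_pred": report.raw_pred,
            "corrected_pred": report.corrected_pred,
        }
    )
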