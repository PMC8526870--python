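"""Individual deviations from normative development.

Z-scores reference each observation to the GP predictive distribution;
|Z| > 3.1 (two one-sided normal p < 0.001) defines an extreme deviation.
Extreme masks are summarised two ways: *overlap maps* (per parcel and
metric, the percentage of a group's infants that are extreme there) and
*atypicality indices* (per infant and metric, the percentage of all parcels
that are extreme — the whole-cortex burden). An infant with 29
extreme-negative parcels out of 286 has a negative atypicality index of
10.14%, i.e. 10% rounded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, t as student_t

from .cohort import METRICS, FeatureTable
from .normative import PredictiveDistribution


def _t_to_normal(ratio: np.ndarray, t_dof: np.ndarray | None) -> np.ndarray:
    """Map Student-t deviation ratios onto the standard-normal scale.

    With the noise variance estimated from n training subjects, the ratio
    (observed - predicted) / sd is t-distributed with the model's effective
    residual degrees of freedom, whose tails are heavier than normal; the
    quantile transform z = Phi^-1(T_dof(ratio)) restores exact normal
    calibration so that |Z| > 3.1 keeps its nominal p < 0.001 meaning.
    Cells without df information (or infinite df) pass through unchanged,
    as do ratios too extreme for the tail computation to resolve.
    """
    if t_dof is None:
        return ratio
    dof = np.broadcast_to(np.asarray(t_dof, dtype=float)[None], ratio.shape)
    finite = np.isfinite(dof)
    if not finite.any():
        return ratio
    out = ratio.copy()
    r = ratio[finite]
    tail = student_t.sf(np.abs(r), dof[finite])
    z = norm.isf(tail)
    ok = np.isfinite(z)  # extreme tails underflow; keep the raw ratio there
    out_vals = np.where(ok, np.sign(r) * z, r)
    out[finite] = out_vals
    return out

#: |Z| beyond this is an extreme deviation (one-sided normal p < 0.001).
EXTREME_THRESHOLD = 3.1


@dataclass
class ZScoreTable:
    """Dimensionless deviations; positive = observed above the normative
    prediction (flip with ``sign_convention='pred_minus_obs'``)."""

    z: np.ndarray  # (n_subjects, n_parcels, n_metrics)
    subject_ids: np.ndarray
    parcel_ids: np.ndarray
    metrics: tuple[str, ...] = METRICS


@dataclass
class ExtremeMask:
    """Three-way labels: +1 (Z > threshold), -1 (Z < -threshold), else 0.
    Strict inequalities: |Z| exactly at the threshold is normative."""

    label: np.ndarray  # int8, same shape as z
    threshold: float
    subject_ids: np.ndarray
    parcel_ids: np.ndarray
    metrics: tuple[str, ...] = METRICS


@dataclass
class OverlapMap:
    """Percentage of the scored group with an extreme deviation per parcel.
    Denominator is the full group size, not per-parcel counts."""

    percent_pos: np.ndarray  # (n_parcels, n_metrics), in [0, 100]
    percent_neg: np.ndarray
    n_group: int
    parcel_ids: np.ndarray
    metrics: tuple[str, ...] = METRICS


@dataclass
class AtypicalityIndex:
    """Whole-cortex burden: percentage of parcels extreme per subject and
    metric, reported unrounded and rounded to integer percent."""

    pos_index: np.ndarray  # (n_subjects, n_metrics), in [0, 100]
    neg_index: np.ndarray
    subject_ids: np.ndarray
    metrics: tuple[str, ...] = METRICS

    @property
    def pos_rounded(self) -> np.ndarray:
        return np.rint(self.pos_index).astype(int)

    @property
    def neg_rounded(self) -> np.ndarray:
        return np.rint(self.neg_index).astype(int)


def compute_z_scores(
    pred: PredictiveDistribution,
    observed: FeatureTable,
    sign_convention: str = "obs_minus_pred",
) -> ZScoreTable:
    """Z = (observed - predictive mean) / sqrt(predictive variance).

    Uses the calibrated predictive variance (noise term corrected for the
    effective degrees of freedom of the normative fit) when the prediction
    provides one. The default sign convention makes positive Z mean
    "observed above the normative curve"; ``'pred_minus_obs'`` flips it.
    """
    if sign_convention not in ("obs_minus_pred", "pred_minus_obs"):
        raise ValueError(f"unknown sign convention {sign_convention!r}")
    if pred.mean.shape != observed.values.shape:
        raise ValueError("prediction and observation shapes differ")
    if not np.array_equal(pred.subject_ids, observed.subject_ids):
        raise ValueError("prediction and observation subjects are not aligned")
    variance = pred.z_variance
    bad = np.argwhere(variance <= 0)
    if bad.size:
        i, p, j = bad[0]
        raise ValueError(
            f"non-positive predictive variance for subject "
            f"{observed.subject_ids[i]!r}, parcel "
            f"{observed.parcels.parcel_ids[p]}, metric {observed.metrics[j]}"
        )
    z = (observed.values - pred.mean) / np.sqrt(variance)
    z = _t_to_normal(z, pred.t_dof)
    if sign_convention == "pred_minus_obs":
        z = -z
    return ZScoreTable(
        z=z,
        subject_ids=observed.subject_ids,
        parcel_ids=observed.parcels.parcel_ids,
        metrics=observed.metrics,
    )


def classify_extremes(
    z: ZScoreTable, threshold: float = EXTREME_THRESHOLD
) -> ExtremeMask:
    """Label each cell +1/-1/0 with strict inequalities at the threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    label = np.zeros(z.z.shape, dtype=np.int8)
    label[z.z > threshold] = 1
    label[z.z < -threshold] = -1
    return ExtremeMask(
        label=label,
        threshold=threshold,
        subject_ids=z.subject_ids,
        parcel_ids=z.parcel_ids,
        metrics=z.metrics,
    )


def overlap_map(mask: ExtremeMask, group_subjects=None) -> OverlapMap:
    """Percentage of the group's infants extreme at each (parcel, metric).

    ``group_subjects`` optionally restricts to a subject-id subset (e.g. the
    preterm group); by default all scored subjects form the group.
    """
    if group_subjects is None:
        sel = np.ones(len(mask.subject_ids), dtype=bool)
    else:
        sel = np.isin(mask.subject_ids, np.asarray(list(group_subjects)))
    n_group = int(sel.sum())
    if n_group == 0:
        raise ValueError("group is empty")
    lab = mask.label[sel]
    percent_pos = 100.0 * (lab == 1).sum(axis=0) / n_group
    percent_neg = 100.0 * (lab == -1).sum(axis=0) / n_group
    return OverlapMap(
        percent_pos=percent_pos,
        percent_neg=percent_neg,
        n_group=n_group,
        parcel_ids=mask.parcel_ids,
        metrics=mask.metrics,
    )


def atypicality_indices(mask: ExtremeMask) -> AtypicalityIndex:
    """Per-subject whole-cortex burden of extreme deviations.

    The denominator is the full parcel count, including any parcels whose
    normative fit was skipped (those carry label 0 and count as normative).
    """
    n_parcels = mask.label.shape[1]
    pos = 100.0 * (mask.label == 1).sum(axis=1) / n_parcels
    neg = 100.0 * (mask.label == -1).sum(axis=1) / n_parcels
    return AtypicalityIndex(
        pos_index=pos,
        neg_index=neg,
        subject_ids=mask.subject_ids,
        metrics=mask.metrics,
    )
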