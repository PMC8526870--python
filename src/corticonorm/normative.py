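"""Gaussian-process normative models of typical cortical development.

One independent GP is fitted per (parcel, metric) cell on term-born training
data, with standardized postmenstrual age at scan and binary sex as
predictors and the cortical feature as output. The covariance is a sum of a
radial basis function, a linear and a white-noise kernel::

    k(x, x') = s_r^2 exp(-||x - x'||^2 / (2 l^2)) + s_l^2 (x . x') + s_n^2 I

Hyperparameters maximise the log marginal likelihood by multi-start L-BFGS-B
on log-parameters. Predictions follow the standard GP posterior; the
predictive variance *includes* the white-noise term so that Z-scores of new
observations are calibrated (a typical new subject should rarely exceed
|Z| > 3.1). Because the maximum-likelihood noise estimate is biased low by
the flexibility of the fitted mean (E[s_n^2] ~ s^2 (n - nu)/n, with nu the
effective degrees of freedom of the GP smoother), the noise term entering
the predictive variance is rescaled by n/(n - nu); without this the pooled
Z variance of held-out typical subjects exceeds 1 and the |Z| > 3.1 rate
overshoots its nominal 0.00194.

Outputs are standardized per cell before fitting and predictions are
de-standardized back to metric units, so hyperparameters are comparable
across cells.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize

from .cohort import METRICS, FeatureTable

logger = logging.getLogger(__name__)

# cell status codes
OK = 0
CONSTANT_FALLBACK = 1
FAILED = 2

_LOG2PI = math.log(2.0 * math.pi)
_JITTER_START = 1e-8
_JITTER_MAX = 1e-4


@dataclass(frozen=True)
class KernelParams:
    """Hyperparameters of the RBF + linear + white-noise kernel (standardized
    output space)."""

    rbf_variance: float
    rbf_lengthscale: float
    linear_variance: float
    noise_variance: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.rbf_variance, self.rbf_lengthscale,
             self.linear_variance, self.noise_variance]
        )


@dataclass
class PredictiveDistribution:
    """Per-cell predictive mean and variance in metric units.

    ``variance`` is the textbook GP posterior variance plus the fitted noise
    variance (for a linear-only kernel it equals the closed-form Bayesian
    linear regression predictive variance). ``variance_calibrated``
    additionally rescales the noise term by the effective-degrees-of-freedom
    factor n/(n - nu) and is what Z-scores of new observations should be
    normalized by.
    """

    mean: np.ndarray  # (n_subjects, n_parcels, n_metrics)
    variance: np.ndarray  # same shape, > 0
    subject_ids: np.ndarray
    metrics: tuple[str, ...] = METRICS
    variance_calibrated: np.ndarray | None = None
    #: effective residual degrees of freedom per (parcel, metric); the
    #: deviation ratio is Student-t with these df, so Z-scoring maps it
    #: through the t-CDF / normal-quantile transform. None or inf = skip.
    t_dof: np.ndarray | None = None

    @property
    def z_variance(self) -> np.ndarray:
        """Variance used for Z-scoring (calibrated when available)."""
        return (
            self.variance_calibrated
            if self.variance_calibrated is not None
            else self.variance
        )


class NormativeModel:
    """Per-(parcel, metric) GP normative model fitted on term-born data."""

    def __init__(
        self,
        params: np.ndarray,  # (n_parcels, n_metrics, 4)
        status: np.ndarray,  # (n_parcels, n_metrics) int
        log_marginal: np.ndarray,  # (n_parcels, n_metrics)
        x_train: np.ndarray,  # (n_train, 2) standardized PMA, raw sex
        y_train_std: np.ndarray,  # (n_train, n_parcels, n_metrics)
        y_mean: np.ndarray,
        y_sd: np.ndarray,
        pma_mean: float,
        pma_sd: float,
        parcel_ids: np.ndarray,
        metrics: tuple[str, ...] = METRICS,
        train_subject_ids: np.ndarray | None = None,
    ) -> None:
        self.params = params
        self.status = status
        self.log_marginal = log_marginal
        self.x_train = x_train
        self.y_train_std = y_train_std
        self.y_mean = y_mean
        self.y_sd = y_sd
        self.pma_mean = pma_mean
        self.pma_sd = pma_sd
        self.parcel_ids = np.asarray(parcel_ids)
        self.metrics = tuple(metrics)
        self.train_subject_ids = (
            np.asarray(train_subject_ids) if train_subject_ids is not None else None
        )

    def kernel_params(self, parcel: int, metric: str) -> KernelParams:
        j = self.metrics.index(metric)
        p = int(np.flatnonzero(self.parcel_ids == parcel)[0])
        return KernelParams(*self.params[p, j])

    def standardize_covariates(self, subjects: pd.DataFrame) -> np.ndarray:
        pma = subjects["pma_scan"].to_numpy(float)
        sex = subjects["sex"].to_numpy(float)
        return np.column_stack([(pma - self.pma_mean) / self.pma_sd, sex])

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "params": self.params.tolist(),
            "status": self.status.tolist(),
            "log_marginal": self.log_marginal.tolist(),
            "x_train": self.x_train.tolist(),
            "y_train_std": self.y_train_std.tolist(),
            "y_mean": self.y_mean.tolist(),
            "y_sd": self.y_sd.tolist(),
            "pma_mean": self.pma_mean,
            "pma_sd": self.pma_sd,
            "parcel_ids": self.parcel_ids.tolist(),
            "metrics": list(self.metrics),
            "train_subject_ids": (
                self.train_subject_ids.tolist()
                if self.train_subject_ids is not None else None
            ),
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "NormativeModel":
        ids = d.get("train_subject_ids")
        return cls(
            params=np.asarray(d["params"]),
            status=np.asarray(d["status"], dtype=int),
            log_marginal=np.asarray(d["log_marginal"]),
            x_train=np.asarray(d["x_train"]),
            y_train_std=np.asarray(d["y_train_std"]),
            y_mean=np.asarray(d["y_mean"]),
            y_sd=np.asarray(d["y_sd"]),
            pma_mean=float(d["pma_mean"]),
            pma_sd=float(d["pma_sd"]),
            parcel_ids=np.asarray(d["parcel_ids"]),
            metrics=tuple(d["metrics"]),
            train_subject_ids=np.asarray(ids) if ids is not None else None,
        )

    @classmethod
    def load(cls, path) -> "NormativeModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def split_cohort(
    subjects: pd.DataFrame, holdout_fraction: float = 0.25, seed: int = 0
) -> pd.Series:
    """Partition term-born subjects into train/holdout, stratified by PMA.

    Subjects are binned into PMA-at-scan quartiles and the holdout quota
    (``round(n * holdout_fraction)``, allocated to strata by largest
    remainder) is drawn within each bin, so the two partitions have matched
    age distributions. Returns a Series mapping subject_id to
    'train'/'holdout'. Deterministic given the seed.
    """
    if not 0.0 < holdout_fraction < 1.0:
        raise ValueError("holdout_fraction must be in (0, 1)")
    n = len(subjects)
    if n < 8:
        raise ValueError("need at least 8 subjects to split")
    rng = np.random.default_rng(seed)
    order = np.argsort(subjects["pma_scan"].to_numpy(), kind="stable")
    strata = np.array_split(order, 4)

    n_hold = int(round(n * holdout_fraction))
    ideal = np.array([len(s) * holdout_fraction for s in strata])
    base = np.floor(ideal).astype(int)
    short = n_hold - base.sum()
    if short > 0:
        extra = np.argsort(-(ideal - base), kind="stable")[:short]
        base[extra] += 1
    elif short < 0:
        give = np.argsort(ideal - base, kind="stable")[: -short]
        base[give] -= 1

    assignment = np.full(n, "train", dtype=object)
    for stratum, k in zip(strata, base):
        pick = rng.permutation(stratum)[:k]
        assignment[pick] = "holdout"
    return pd.Series(assignment, index=subjects["subject_id"].to_numpy(), name="split")


# ---------------------------------------------------------------------------
# GP internals (single cell, standardized output)
# ---------------------------------------------------------------------------

def _neg_lml_and_grad(log_theta, d2, xxt, y, jitter):
    """Negative log marginal likelihood and gradient w.r.t. log-params."""
    rv, ls, lv, nv = np.exp(log_theta)
    E = np.exp(-0.5 * d2 / (ls * ls))
    K = rv * E + lv * xxt
    n = y.shape[0]
    K.flat[:: n + 1] += nv + jitter
    try:
        L = cholesky(K, lower=True)
    except np.linalg.LinAlgError:
        return 1e25, np.zeros(4)
    alpha = cho_solve((L, True), y)
    nll = 0.5 * float(y @ alpha) + float(np.log(np.diag(L)).sum()) + 0.5 * n * _LOG2PI
    Kinv = cho_solve((L, True), np.eye(n))
    A = np.outer(alpha, alpha) - Kinv  # dLML/dK = 0.5 * A
    g = np.empty(4)
    g[0] = -0.5 * rv * float(np.sum(A * E))
    g[1] = -0.5 * rv * float(np.sum(A * (E * d2))) / (ls * ls)
    g[2] = -0.5 * lv * float(np.sum(A * xxt))
    g[3] = -0.5 * nv * float(np.trace(A))
    return nll, g


_LOG_BOUNDS = [
    (math.log(1e-6), math.log(1e3)),  # rbf variance
    (math.log(1e-2), math.log(1e2)),  # rbf lengthscale
    (math.log(1e-8), math.log(1e3)),  # linear variance
    (math.log(_JITTER_START), math.log(1e2)),  # noise variance
]


def _initial_points(restarts: int, rng: np.random.Generator) -> np.ndarray:
    """Deterministic first start, then seeded log-normal perturbations with
    the lengthscale cycling through {0.5, 1, 2} (covariates are standardized)."""
    base = np.log([0.5, 1.0, 0.5, 0.5])
    inits = [base]
    scales = [0.5, 1.0, 2.0]
    for i in range(1, restarts):
        pt = base + rng.normal(0.0, 0.7, size=4)
        pt[1] = math.log(scales[i % 3]) + rng.normal(0.0, 0.3)
        inits.append(pt)
    return np.array(inits)


def _fit_cell(y_std, d2, xxt, inits):
    """Fit one standardized cell; returns (params, best_nll, init_nlls, ok)."""
    best = None
    init_nlls = []
    for x0 in inits:
        nll0, _ = _neg_lml_and_grad(x0, d2, xxt, y_std, _JITTER_START)
        init_nlls.append(nll0)
        res = minimize(
            _neg_lml_and_grad,
            x0,
            args=(d2, xxt, y_std, _JITTER_START),
            jac=True,
            method="L-BFGS-B",
            bounds=_LOG_BOUNDS,
            options={"maxiter": 120},
        )
        if best is None or res.fun < best.fun:
            best = res
    ok = np.isfinite(best.fun) and best.fun < 1e24
    return np.exp(best.x), -best.fun, init_nlls, ok


def fit_normative_model(
    train_table: FeatureTable, restarts: int = 5, seed: int = 0
) -> NormativeModel:
    """Fit an independent GP per (parcel, metric) on the training table.

    Cells whose output is constant fall back to a noise-only model; cells
    whose covariance cannot be factorised even after jitter escalation are
    flagged as failed and skipped (status recorded, other cells continue).
    """
    subjects = train_table.subjects
    if len(subjects) < 10:
        raise ValueError("need at least 10 training subjects")
    pma = subjects["pma_scan"].to_numpy(float)
    pma_mean, pma_sd = float(pma.mean()), float(pma.std(ddof=0))
    if pma_sd <= 0:
        raise ValueError("PMA at scan is constant in the training sample")
    X = np.column_stack([(pma - pma_mean) / pma_sd, subjects["sex"].to_numpy(float)])

    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    xxt = X @ X.T

    n_s, n_p, n_m = train_table.values.shape
    y_mean = train_table.values.mean(axis=0)
    y_sd = train_table.values.std(axis=0, ddof=0)

    params = np.zeros((n_p, n_m, 4))
    status = np.zeros((n_p, n_m), dtype=int)
    log_marginal = np.full((n_p, n_m), -np.inf)

    rng = np.random.default_rng(seed)
    inits = _initial_points(restarts, rng)

    n_failed = 0
    for p in range(n_p):
        for j in range(n_m):
            sd = y_sd[p, j]
            if sd < 1e-12:
                # constant output: noise-only fallback
                status[p, j] = CONSTANT_FALLBACK
                params[p, j] = (0.0, 1.0, 0.0, _JITTER_START)
                continue
            y_std = (train_table.values[:, p, j] - y_mean[p, j]) / sd
            theta, lml, init_nlls, ok = _fit_cell(y_std, d2, xxt, inits)
            if not ok:
                status[p, j] = FAILED
                n_failed += 1
                logger.warning(
                    "GP fit failed for parcel %d metric %s",
                    train_table.parcels.parcel_ids[p], train_table.metrics[j],
                )
                continue
            params[p, j] = theta
            log_marginal[p, j] = lml
    if n_failed:
        logger.warning("%d of %d cells failed to fit", n_failed, n_p * n_m)

    y_train_std = (train_table.values - y_mean) / np.where(y_sd < 1e-12, 1.0, y_sd)
    return NormativeModel(
        params=params,
        status=status,
        log_marginal=log_marginal,
        x_train=X,
        y_train_std=y_train_std,
        y_mean=y_mean,
        y_sd=y_sd,
        pma_mean=pma_mean,
        pma_sd=pma_sd,
        parcel_ids=train_table.parcels.parcel_ids,
        metrics=train_table.metrics,
        train_subject_ids=train_table.subject_ids,
    )


def _cell_posterior(theta, X, Xs, y_std, d2_train):
    """GP posterior for one cell (standardized space).

    The additive noise term in the predictive variance is rescaled by
    n / (n - nu), where nu = n - s_n^2 tr[(K + s_n^2 I)^-1] is the effective
    degrees of freedom of the smoother, undoing the downward bias of the
    maximum-likelihood noise estimate (the factor is capped at 2 as a guard
    against nearly interpolating fits).
    """
    rv, ls, lv, nv = theta
    n = X.shape[0]
    K = rv * np.exp(-0.5 * d2_train / (ls * ls)) + lv * (X @ X.T)
    jitter = _JITTER_START
    while True:
        Kj = K.copy()
        Kj.flat[:: n + 1] += nv + jitter
        try:
            L = cholesky(Kj, lower=True)
            break
        except np.linalg.LinAlgError:
            jitter *= 100.0
            if jitter > _JITTER_MAX:
                raise
    d2_cross = ((Xs[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    Ks = rv * np.exp(-0.5 * d2_cross / (ls * ls)) + lv * (Xs @ X.T)
    alpha = cho_solve((L, True), y_std)
    mean = Ks @ alpha
    V = solve_triangular(L, Ks.T, lower=True)
    prior_diag = rv + lv * (Xs * Xs).sum(-1)

    trace_kinv = float(np.trace(cho_solve((L, True), np.eye(n))))
    nu = n - nv * trace_kinv
    resid_dof = max(n - nu, 3.0)
    dof_factor = min(n / resid_dof, 2.0)
    fit_var = prior_diag - (V * V).sum(0)
    var = fit_var + nv
    var_cal = fit_var + nv * dof_factor
    return mean, np.maximum(var, 1e-12), np.maximum(var_cal, 1e-12), resid_dof


def predict(model: NormativeModel, subjects: pd.DataFrame) -> PredictiveDistribution:
    """GP posterior mean/variance in metric units for new covariate rows.

    Warns (never refuses) when a subject's PMA falls more than one week
    outside the training range. Raises for cells whose fit failed, naming
    the (parcel, metric).
    """
    n_new = len(subjects)
    n_p, n_m = model.y_mean.shape
    if n_new == 0:
        empty = np.empty((0, n_p, n_m))
        return PredictiveDistribution(
            mean=empty, variance=empty.copy(),
            subject_ids=np.array([], dtype=object), metrics=model.metrics,
            variance_calibrated=empty.copy(),
        )
    Xs = model.standardize_covariates(subjects)
    pma = subjects["pma_scan"].to_numpy(float)
    tr_pma = model.x_train[:, 0] * model.pma_sd + model.pma_mean
    if np.any(pma < tr_pma.min() - 1.0) or np.any(pma > tr_pma.max() + 1.0):
        warnings.warn(
            "PMA at scan more than 1 week outside the training range; "
            "normative predictions are extrapolations",
            stacklevel=2,
        )

    failed = np.argwhere(model.status == FAILED)
    if failed.size:
        p, j = failed[0]
        raise ValueError(
            f"normative model unfitted for parcel {model.parcel_ids[p]} "
            f"metric {model.metrics[j]}"
        )

    X = model.x_train
    d2_train = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    mean = np.empty((n_new, n_p, n_m))
    var = np.empty((n_new, n_p, n_m))
    var_cal = np.empty((n_new, n_p, n_m))
    t_dof = np.full((n_p, n_m), np.inf)
    for p in range(n_p):
        for j in range(n_m):
            if model.status[p, j] == CONSTANT_FALLBACK:
                mean[:, p, j] = model.y_mean[p, j]
                var[:, p, j] = 1e-12
                var_cal[:, p, j] = 1e-12
                continue
            m_std, v_std, vc_std, dof = _cell_posterior(
                model.params[p, j], X, Xs, model.y_train_std[:, p, j], d2_train
            )
            sd = model.y_sd[p, j]
            mean[:, p, j] = m_std * sd + model.y_mean[p, j]
            var[:, p, j] = v_std * sd * sd
            var_cal[:, p, j] = vc_std * sd * sd
            t_dof[p, j] = dof
    return PredictiveDistribution(
        mean=mean, variance=var,
        subject_ids=subjects["subject_id"].to_numpy(), metrics=model.metrics,
        variance_calibrated=var_cal, t_dof=t_dof,
    )


def evaluate_mae(model: NormativeModel, holdout_table: FeatureTable) -> np.ndarray:
    """Mean absolute error between predictions and held-out observations.

    Returns an (n_parcels, n_metrics) map in metric units. Refuses if any
    holdout subject was in the training sample.
    """
    if model.train_subject_ids is not None:
        overlap = np.intersect1d(model.train_subject_ids, holdout_table.subject_ids)
        if overlap.size:
            raise ValueError(
                f"holdout overlaps the training sample: {overlap[:5].tolist()}"
            )
    pred = predict(model, holdout_table.subjects)
    return np.abs(holdout_table.values - pred.mean).mean(axis=0)
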