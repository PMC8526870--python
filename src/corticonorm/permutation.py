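"""Max-statistic permutation GLM inference with Freedman-Lane residuals.

Per (parcel, metric) cell an OLS model is fitted and the t-statistic of one
tested coefficient is evaluated against a permutation distribution built by
the Freedman-Lane scheme: the data are residualized against the nuisance
columns, the residuals are row-permuted, and the full model is refitted.
For each permutation the maximum statistic over *all* parcels x metrics x
contrasts is recorded, so the resulting p-values are family-wise error
corrected jointly across parcels, the 8 modalities and the +/- contrast
pair ("p_mcfwe"). The two one-sided contrasts are read off one max-|t|
distribution, which is equivalent to and cheaper than two separate runs.

The identity permutation is included, giving the +1/+1 convention
p = (1 + #{max >= t_obs}) / (1 + n_perm), so p is always in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import FeatureTable

#: sentinel |t| for cells with (numerically) zero residual variance
T_CAP = 1e6

_MIN_PERMUTATIONS = 100


@dataclass
class DesignMatrix:
    """GLM design: ``matrix`` (subjects x columns), column names, and the
    name of the single tested column; all other columns are nuisance."""

    matrix: np.ndarray
    columns: list[str]
    tested: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.tested not in self.columns:
            raise ValueError(f"tested column {self.tested!r} not in design")
        rank = np.linalg.matrix_rank(self.matrix)
        if rank < self.matrix.shape[1]:
            # identify offending columns from the QR diagonal
            R = np.linalg.qr(self.matrix, mode="r")
            diag = np.abs(np.diag(R))
            tol = diag.max() * 1e-10 if diag.size else 0.0
            bad = [c for c, d in zip(self.columns, diag) if d <= tol]
            raise ValueError(f"design matrix is rank deficient; collinear: {bad}")

    @property
    def tested_index(self) -> int:
        return self.columns.index(self.tested)


def _subject_frame(subjects) -> pd.DataFrame:
    return subjects.subjects if isinstance(subjects, FeatureTable) else subjects


def design_age(subjects: pd.DataFrame) -> DesignMatrix:
    """PMA-at-scan association with sex as nuisance (single-group design)."""
    s = _subject_frame(subjects)
    M = np.column_stack(
        [np.ones(len(s)), s["pma_scan"].to_numpy(float), s["sex"].to_numpy(float)]
    )
    return DesignMatrix(M, ["intercept", "pma_scan", "sex"], "pma_scan")


def design_group(subjects: pd.DataFrame) -> DesignMatrix:
    """Preterm-vs-term mean difference with PMA and sex as nuisance."""
    s = _subject_frame(subjects)
    group = (s["group"] == "preterm").astype(float).to_numpy()
    M = np.column_stack(
        [np.ones(len(s)), group, s["pma_scan"].to_numpy(float),
         s["sex"].to_numpy(float)]
    )
    return DesignMatrix(M, ["intercept", "group", "pma_scan", "sex"], "group")


def design_interaction(subjects: pd.DataFrame) -> DesignMatrix:
    """Group x PMA slope difference; PMA is centered before the product and
    group, PMA and sex main effects are nuisance."""
    s = _subject_frame(subjects)
    group = (s["group"] == "preterm").astype(float).to_numpy()
    pma_c = s["pma_scan"].to_numpy(float) - s["pma_scan"].to_numpy(float).mean()
    M = np.column_stack([np.ones(len(s)), group, pma_c, s["sex"].to_numpy(float),
                         group * pma_c])
    return DesignMatrix(
        M, ["intercept", "group", "pma_scan_c", "sex", "group_x_pma"], "group_x_pma"
    )


def design_covariate(
    subjects: pd.DataFrame, covariate: str, nuisance: tuple[str, ...] = ("sex",)
) -> DesignMatrix:
    """Association with an arbitrary subject covariate (GA at birth, BSID
    scores, ...) adjusting for the named nuisance columns."""
    s = _subject_frame(subjects)
    x = s[covariate].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError(f"covariate {covariate!r} is constant")
    cols = [np.ones(len(s)), x] + [s[c].to_numpy(float) for c in nuisance]
    names = ["intercept", covariate] + list(nuisance)
    return DesignMatrix(np.column_stack(cols), names, covariate)


@dataclass
class StatMap:
    """Observed per-cell statistics: t for the tested coefficient and the
    bivariate Pearson correlation between tested covariate and feature
    (reported alongside significant parcels by convention); ``partial_r``
    is the nuisance-adjusted alternative, t/sqrt(t^2 + df)."""

    t: np.ndarray
    r: np.ndarray
    df: int
    metrics: tuple[str, ...] | None = None

    @property
    def partial_r(self) -> np.ndarray:
        return self.t / np.sqrt(self.t**2 + self.df)


@dataclass
class PermutationResult:
    """Family-wise-error corrected permutation inference for a +/- contrast
    pair on one tested coefficient."""

    t: np.ndarray  # observed t per cell
    r: np.ndarray  # bivariate Pearson r per cell
    p_pos: np.ndarray  # corrected p, positive contrast (t > 0 direction)
    p_neg: np.ndarray  # corrected p, negative contrast
    df: int
    n_perm: int
    seed: int
    alpha: float = 0.05
    max_stats: np.ndarray | None = None  # permutation max-|t| distribution

    @property
    def partial_r(self) -> np.ndarray:
        """Nuisance-adjusted correlation of the tested coefficient."""
        return self.t / np.sqrt(self.t**2 + self.df)

    @property
    def significant_pos(self) -> np.ndarray:
        return self.p_pos < self.alpha

    @property
    def significant_neg(self) -> np.ndarray:
        return self.p_neg < self.alpha

    @property
    def significant(self) -> np.ndarray:
        return self.significant_pos | self.significant_neg


def _as_matrix(table) -> tuple[np.ndarray, tuple[int, ...]]:
    values = table.values if isinstance(table, FeatureTable) else np.asarray(
        getattr(table, "z", table), dtype=float
    )
    shape = values.shape
    return values.reshape(shape[0], -1), shape[1:]


def _glm_stats(Y: np.ndarray, design: DesignMatrix):
    """Observed t (tested coefficient) and Pearson r per column of Y."""
    M = design.matrix
    n, p = M.shape
    k = design.tested_index
    x = M[:, k]
    Z = np.delete(M, k, axis=1)
    Qz, _ = np.linalg.qr(Z)
    x_res = x - Qz @ (Qz.T @ x)
    nx2 = float(x_res @ x_res)
    if nx2 <= 1e-12 * float(x @ x):
        raise ValueError(
            f"tested column {design.tested!r} is collinear with the nuisance"
        )
    df = n - p
    Y_res = Y - Qz @ (Qz.T @ Y)
    a = x_res @ Y_res
    rss = (Y_res * Y_res).sum(axis=0) - a * a / nx2
    sigma2 = rss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = a / np.sqrt(nx2 * sigma2)
    degenerate = sigma2 <= 1e-12 * np.maximum((Y * Y).sum(0) / n, 1e-300)
    t = np.where(degenerate, np.sign(a) * T_CAP, t)

    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    denom = np.sqrt((xc @ xc) * (Yc * Yc).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, xc @ Yc / np.where(denom > 0, denom, 1.0), 0.0)
    return t, r, df, Qz, x_res, nx2, Y_res


def fit_glm(table, design: DesignMatrix) -> StatMap:
    """Per-cell OLS t-statistic for the tested coefficient plus the simple
    bivariate Pearson correlation (perfect fits are capped at ``T_CAP``)."""
    Y, cell_shape = _as_matrix(table)
    n, p = design.matrix.shape
    if n != Y.shape[0]:
        raise ValueError("design and data have different numbers of subjects")
    if n < p + 1:
        raise ValueError("need residual degrees of freedom (n > design columns)")
    t, r, df, *_ = _glm_stats(Y, design)
    metrics = getattr(table, "metrics", None)
    return StatMap(t=t.reshape(cell_shape), r=r.reshape(cell_shape), df=df,
                   metrics=metrics)


def permutation_test(
    table,
    design: DesignMatrix,
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> PermutationResult:
    """Freedman-Lane max-statistic permutation test for one tested column.

    Returns corrected p-values for the positive and negative one-sided
    contrasts, jointly FWE-corrected across every cell and both contrasts.
    """
    if n_perm < _MIN_PERMUTATIONS:
        raise ValueError(
            f"n_perm must be at least {_MIN_PERMUTATIONS} for a stable tail"
        )
    Y, cell_shape = _as_matrix(table)
    n, p = design.matrix.shape
    if n != Y.shape[0]:
        raise ValueError("design and data have different numbers of subjects")
    if n < p + 2:
        raise ValueError("need at least 2 more subjects than design columns")

    t_obs, r, df, Qz, x_res, nx2, Y_res = _glm_stats(Y, design)

    # Permuting the nuisance-residualized data and refitting the full model
    # reduces (Frisch-Waugh) to projections onto x_res and the nuisance
    # basis; ||Y_res|| is permutation-invariant, so each permutation costs
    # two thin matrix products.
    ss_y = (Y_res * Y_res).sum(axis=0)
    proj = np.column_stack([x_res, Qz])  # n x (1 + q)
    rng = np.random.default_rng(seed)
    max_stats = np.empty(n_perm)
    scale = np.sqrt(nx2)
    for b in range(n_perm):
        perm = rng.permutation(n)
        B = proj.T @ Y_res[perm]
        a = B[0]
        rss = ss_y - (B[1:] * B[1:]).sum(axis=0) - a * a / nx2
        sigma2 = np.maximum(rss, 0.0) / df
        with np.errstate(divide="ignore", invalid="ignore"):
            t_b = a / (scale * np.sqrt(sigma2))
        t_b = np.where(np.isfinite(t_b), t_b, T_CAP)
        max_stats[b] = np.abs(t_b).max()

    # +1/+1 convention; the identity permutation is the "+1"
    exceed_pos = (max_stats[:, None] >= t_obs[None, :]).sum(axis=0)
    exceed_neg = (max_stats[:, None] >= -t_obs[None, :]).sum(axis=0)
    p_pos = (1.0 + exceed_pos) / (1.0 + n_perm)
    p_neg = (1.0 + exceed_neg) / (1.0 + n_perm)

    return PermutationResult(
        t=t_obs.reshape(cell_shape),
        r=r.reshape(cell_shape),
        p_pos=p_pos.reshape(cell_shape),
        p_neg=p_neg.reshape(cell_shape),
        df=df,
        n_perm=n_perm,
        seed=seed,
        alpha=alpha,
        max_stats=max_stats,
    )


def interaction_test(
    table,
    subjects: pd.DataFrame | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> PermutationResult:
    """Group x PMA interaction test (slope difference between groups).

    Convenience wrapper: builds the centered-interaction design from the
    subject table (defaults to the table's own subjects) and delegates to
    :func:`permutation_test` with the interaction coefficient tested and the
    main effects as nuisance.
    """
    if subjects is None:
        if not isinstance(table, FeatureTable):
            raise ValueError("subjects must be given unless table is a FeatureTable")
        subjects = table.subjects
    design = design_interaction(subjects)
    return permutation_test(table, design, n_perm=n_perm, seed=seed, alpha=alpha)
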