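"""Deviations versus age at birth and 18-month outcome.

Parcel-wise Z-score associations reuse the permutation GLM (gestational age
at birth or a BSID-III composite as the tested covariate, sex — plus
optionally PMA — as nuisance). Whole-cortex atypicality indices, which are
heavily tied percentages, are analysed with rank statistics: Kendall tau-b
for correlation with a covariate, Mann-Whitney U for term/preterm group
differences, with Benjamini-Hochberg FDR over each family of
(metric x index-sign) hypotheses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import kendalltau, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .deviations import AtypicalityIndex, ZScoreTable
from .permutation import PermutationResult, design_covariate, permutation_test


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def z_covariate_map(
    z: ZScoreTable,
    subjects: pd.DataFrame,
    covariate: str,
    nuisance: tuple[str, ...] = ("sex",),
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> PermutationResult:
    """Permutation-GLM map of Z-scores against a subject covariate.

    ``subjects`` must be aligned with (and is re-indexed to) the Z-table's
    subjects; run it separately on the preterm, term-holdout and combined
    samples by passing the corresponding subsets.
    """
    s = subjects.set_index("subject_id").loc[z.subject_ids].reset_index()
    design = design_covariate(s, covariate, nuisance=nuisance)
    return permutation_test(z, design, n_perm=n_perm, seed=seed, alpha=alpha)


def _index_frame(indices: AtypicalityIndex) -> pd.DataFrame:
    rows = []
    for sign, arr in (("pos", indices.pos_index), ("neg", indices.neg_index)):
        for j, metric in enumerate(indices.metrics):
            rows.append((metric, sign, arr[:, j]))
    return pd.DataFrame(rows, columns=["metric", "sign", "values"])


def index_correlation(
    indices: AtypicalityIndex, covariate: np.ndarray, covariate_name: str = ""
) -> pd.DataFrame:
    """Kendall tau-b between each (metric, sign) atypicality index and the
    covariate, BH-FDR corrected over the whole family.

    Uses the exact null distribution for n <= 50 without ties, otherwise the
    tie-corrected normal approximation. All-tied indices are reported with
    NaN tau and a reason instead of failing the family.
    """
    cov = np.asarray(covariate, dtype=float)
    n = cov.size
    if n < 5:
        raise ValueError("need at least 5 subjects")
    if len(indices.subject_ids) != n:
        raise ValueError("covariate length does not match the index table")
    rows = []
    for _, rec in _index_frame(indices).iterrows():
        vals = rec["values"]
        if np.ptp(vals) == 0:
            rows.append(
                dict(metric=rec["metric"], sign=rec["sign"], kendall_tau=np.nan,
                     p_raw=np.nan, n=n, note="all index values tied")
            )
            continue
        method = "exact" if (n <= 50 and _no_ties(vals, cov)) else "asymptotic"
        res = kendalltau(cov, vals, method=method)
        rows.append(
            dict(metric=rec["metric"], sign=rec["sign"],
                 kendall_tau=float(res.statistic), p_raw=float(res.pvalue),
                 n=n, note="")
        )
    frame = pd.DataFrame(rows)
    frame["p_fdr"] = _fdr_with_missing(frame["p_raw"].to_numpy())
    if covariate_name:
        frame.insert(0, "covariate", covariate_name)
    return frame


def _no_ties(a, b) -> bool:
    return len(np.unique(a)) == len(a) and len(np.unique(b)) == len(b)


def _fdr_with_missing(p: np.ndarray) -> np.ndarray:
    out = np.full_like(p, np.nan, dtype=float)
    valid = ~np.isnan(p)
    if valid.any():
        out[valid] = bh_fdr(p[valid])
    return out


def index_group_test(
    indices: AtypicalityIndex, groups: np.ndarray
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U (preterm vs term) per (metric, sign) index,
    BH-FDR corrected. ``groups`` is an array of 'term'/'preterm' labels
    aligned with the index table's subjects; U is reported for the preterm
    group. Exact p for small tie-free samples, tie-corrected normal
    approximation otherwise (scipy's automatic choice)."""
    groups = np.asarray(groups)
    pre = groups == "preterm"
    term = ~pre
    if pre.sum() < 2 or term.sum() < 2:
        raise ValueError("both groups need at least 2 subjects")
    rows = []
    for _, rec in _index_frame(indices).iterrows():
        a = rec["values"][pre]
        b = rec["values"][term]
        res = mannwhitneyu(a, b, alternative="two-sided", method="auto")
        rows.append(
            dict(metric=rec["metric"], sign=rec["sign"],
                 mann_whitney_u=float(res.statistic), p_raw=float(res.pvalue),
                 n_preterm=int(pre.sum()), n_term=int(term.sum()))
        )
    frame = pd.DataFrame(rows)
    frame["p_fdr"] = bh_fdr(frame["p_raw"].to_numpy())
    return frame
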