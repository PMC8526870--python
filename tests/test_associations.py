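"""Outcome associations: Kendall tau, Mann-Whitney U, FDR, Z-score maps."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corticonorm.associations import (
    bh_fdr,
    index_correlation,
    index_group_test,
    z_covariate_map,
)
from corticonorm.deviations import AtypicalityIndex, ZScoreTable


def _indices(pos, metrics=("FA",)):
    pos = np.asarray(pos, dtype=float)
    if pos.ndim == 1:
        pos = pos[:, None]
    ids = np.array([f"s{i}" for i in range(pos.shape[0])])
    return AtypicalityIndex(pos_index=pos, neg_index=np.zeros_like(pos),
                            subject_ids=ids, metrics=metrics)


def _brute_force_tau(x, y):
    """Pair-enumeration oracle for Kendall tau (no ties)."""
    conc = disc = 0
    for (i, j) in itertools.combinations(range(len(x)), 2):
        s = np.sign((x[i] - x[j]) * (y[i] - y[j]))
        conc += s > 0
        disc += s < 0
    return (conc - disc) / (len(x) * (len(x) - 1) / 2)


class TestKendall:
    @pytest.mark.parametrize(
        "x,y,tau",
        [
            ([1, 2, 3, 4, 5], [1, 2, 3, 4, 5], 1.0),
            ([1, 2, 3, 4, 5], [5, 4, 3, 2, 1], -1.0),
            ([1, 2, 3, 4, 5], [1, 3, 2, 4, 5], None),  # oracle-checked
        ],
    )
    def test_against_pair_enumeration(self, x, y, tau):
        frame = index_correlation(_indices(y), np.asarray(x, dtype=float))
        got = frame.loc[frame.sign == "pos", "kendall_tau"].iloc[0]
        expected = tau if tau is not None else _brute_force_tau(x, y)
        assert np.isclose(got, expected)

    def test_four_point_example(self):
        # (1,2,3,4) vs (1,3,2,4): 5 concordant, 1 discordant of 6 pairs
        x, y = [1, 2, 3, 4, 5], [1, 3, 2, 4, 5]
        assert np.isclose(_brute_force_tau([1, 2, 3, 4], [1, 3, 2, 4]), 2 / 3)
        frame = index_correlation(_indices([1, 3, 2, 4, 5]),
                                  np.array([1.0, 2, 3, 4, 5]))
        got = frame.loc[frame.sign == "pos", "kendall_tau"].iloc[0]
        assert np.isclose(got, _brute_force_tau(x, y))

    def test_all_tied_reported_as_missing(self):
        frame = index_correlation(_indices(np.zeros(8)), np.arange(8.0))
        row = frame[frame.sign == "pos"].iloc[0]
        assert np.isnan(row.kendall_tau)
        assert "tied" in row.note

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        f1 = index_correlation(_indices(y), x)
        f2 = index_correlation(_indices(np.exp(y)), x)  # strictly monotone
        np.testing.assert_allclose(
            f1.kendall_tau.to_numpy(), f2.kendall_tau.to_numpy(), atol=1e-12
        )

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="5 subjects"):
            index_correlation(_indices([1, 2, 3]), np.array([1.0, 2, 3]))


class TestMannWhitney:
    def test_complete_separation_exact_p(self):
        # (1,2,3) vs (4,5,6): U = 0 for the low group, exact two-sided
        # p = 2/C(6,3)*... = 0.1 by enumeration of the 20 orderings
        pos = np.array([1.0, 2, 3, 4, 5, 6])
        idx = _indices(pos)
        groups = np.array(["preterm"] * 3 + ["term"] * 3)
        frame = index_group_test(idx, groups)
        row = frame[frame.sign == "pos"].iloc[0]
        assert row.mann_whitney_u == 0.0
        assert np.isclose(row.p_raw, 0.1)

    def test_identical_groups_p_near_one(self):
        pos = np.array([1.0, 2, 3, 1, 2, 3])
        groups = np.array(["preterm"] * 3 + ["term"] * 3)
        frame = index_group_test(_indices(pos), groups)
        assert frame[frame.sign == "pos"].p_raw.iloc[0] > 0.9

    def test_u_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 10, 20)
        groups = np.array(["preterm"] * 9 + ["term"] * 11)
        f1 = index_group_test(_indices(pos), groups)
        f2 = index_group_test(_indices(pos**3), groups)  # monotone on [0,10]
        assert np.array_equal(f1.mann_whitney_u, f2.mann_whitney_u)

    def test_preterm_burden_higher_on_default_cohort(
        self, small_cohort, term_model
    ):
        # preterm infants carry injected extremes, term holdout does not:
        # the preterm group should show higher atypicality indices
        from corticonorm.deviations import atypicality_indices, classify_extremes, compute_z_scores
        from corticonorm.normative import predict

        table, _, _ = small_cohort
        model, _, holdout = term_model
        pre_ids = table.subjects.loc[table.subjects.group == "preterm", "subject_id"]
        scored = table.subset(list(holdout.subject_ids) + list(pre_ids))
        z = compute_z_scores(predict(model, scored.subjects), scored)
        idx = atypicality_indices(classify_extremes(z))
        groups = scored.subjects.group.to_numpy()
        pre_mean = (idx.pos_index + idx.neg_index)[groups == "preterm"].mean()
        term_mean = (idx.pos_index + idx.neg_index)[groups == "term"].mean()
        assert pre_mean > term_mean

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            index_group_test(_indices([1.0, 2, 3]), np.array(["term"] * 3))


class TestBhFdr:
    def test_step_up_worked_example(self):
        # hand-applied BH rule: all four adjusted to 0.04
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_degenerate(self):
        assert bh_fdr([0.37])[0] == 0.37
        assert (bh_fdr([1.0, 1.0, 1.0]) == 1.0).all()

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=25)
        adj = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestZCovariateMap:
    def test_ga_association_recovers_effect_parcels(self, small_parcellation):
        # preterm MD effect scales with prematurity, so GA at birth predicts
        # Z in the configured posterior parcels
        from corticonorm import default_effect_config, generate_features, sample_demographics
        from corticonorm.cohort import METRICS, REGIONS
        from corticonorm.deviations import compute_z_scores
        from corticonorm.normative import fit_normative_model, predict

        subjects = sample_demographics(80, 60, seed=51)
        pe = {m: {r: 0.0 for r in REGIONS} for m in METRICS}
        pe["MD"] = {r: (0.30 if r in ("parietal", "occipital") else 0.0)
                    for r in REGIONS}
        cfg = default_effect_config(seed=52, extreme_rate=0.0, preterm_effect=pe)
        table, truth = generate_features(subjects, small_parcellation, cfg)
        term_ids = subjects.loc[subjects.group == "term", "subject_id"]
        pre_ids = subjects.loc[subjects.group == "preterm", "subject_id"]
        model = fit_normative_model(table.subset(term_ids), restarts=2, seed=53)
        scored = table.subset(pre_ids)
        z = compute_z_scores(predict(model, scored.subjects), scored)
        res = z_covariate_map(z, scored.subjects, "ga_birth", n_perm=500, seed=54)
        j = METRICS.index("MD")
        effect = np.isin(small_parcellation.parcel_ids, truth.effect_parcels["MD"])
        # lower GA -> higher MD deviation: negative association contrast
        sensitivity = res.significant_neg[effect, j].mean()
        assert sensitivity >= 0.8
        assert res.significant[~effect].mean() < 0.05

    def test_shuffled_covariate_finds_nothing(self, small_cohort, term_model):
        from corticonorm.deviations import compute_z_scores
        from corticonorm.normative import predict

        table, _, _ = small_cohort
        model, _, holdout = term_model
        z = compute_z_scores(predict(model, holdout.subjects), holdout)
        subs = holdout.subjects.copy()
        rng = np.random.default_rng(55)
        subs["ga_birth"] = rng.permutation(subs["ga_birth"].to_numpy())
        res = z_covariate_map(z, subs, "ga_birth", n_perm=300, seed=56)
        assert res.significant.sum() <= 2
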