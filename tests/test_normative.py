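"""GP normative model: splitting, hyperparameter recovery, posterior math."""

import numpy as np
import pandas as pd
import pytest

from corticonorm import sample_demographics
from corticonorm.normative import (
    evaluate_mae,
    fit_normative_model,
    predict,
    split_cohort,
)
from corticonorm.validation import _linear_only_model, gp_blr_agreement

from conftest import make_single_cell_table


class TestSplitCohort:
    def test_holdout_count_within_one_of_quarter(self):
        subs = sample_demographics(259, 0, seed=1)
        split = split_cohort(subs, 0.25, seed=1)
        n_hold = (split == "holdout").sum()
        assert abs(n_hold - 0.25 * 259) <= 1
        assert n_hold + (split == "train").sum() == 259

    def test_rounding_on_small_sample(self):
        subs = sample_demographics(8, 0, seed=2)
        split = split_cohort(subs, 0.25, seed=1)
        assert (split == "holdout").sum() == 2
        assert (split == "train").sum() == 6

    def test_partitions_exactly_and_deterministically(self):
        subs = sample_demographics(40, 0, seed=3)
        s1 = split_cohort(subs, 0.25, seed=5)
        s2 = split_cohort(subs, 0.25, seed=5)
        pd.testing.assert_series_equal(s1, s2)
        assert set(s1.index) == set(subs.subject_id)

    def test_stratification_matches_age_distributions(self):
        # stratified splits balance train/holdout PMA better than random
        # splits, on average over seeds
        subs = sample_demographics(80, 0, seed=4)
        pma = subs.set_index("subject_id").pma_scan
        strat_gaps, naive_gaps = [], []
        rng = np.random.default_rng(0)
        for seed in range(60):
            split = split_cohort(subs, 0.25, seed=seed)
            strat_gaps.append(
                abs(pma[split == "train"].mean() - pma[split == "holdout"].mean())
            )
            perm = rng.permutation(len(subs))
            hold = perm[:20]
            naive = np.full(len(subs), "train", dtype=object)
            naive[hold] = "holdout"
            naive_gaps.append(
                abs(pma[naive == "train"].mean() - pma[naive == "holdout"].mean())
            )
        assert np.mean(strat_gaps) < np.mean(naive_gaps)

    def test_invalid_fraction(self):
        subs = sample_demographics(20, 0, seed=1)
        with pytest.raises(ValueError):
            split_cohort(subs, 1.5, seed=1)


class TestFitNormativeModel:
    def test_parameter_recovery_on_linear_data(self):
        # y = 2 * pma_std + noise(sd 0.1): noise variance and slope recovered
        rng = np.random.default_rng(0)
        n = 100
        pma = rng.uniform(37, 45, n)
        pma_std = (pma - pma.mean()) / pma.std()
        y = 2.0 * pma_std + rng.normal(0, 0.1, n)
        table = make_single_cell_table(y, pma)
        model = fit_normative_model(table, restarts=3, seed=1)

        y_sd = table.values[:, 0, 0].std()
        noise_var = model.params[0, 0, 3] * y_sd**2
        assert 0.005 <= noise_var <= 0.02

        lo = table.subjects.iloc[:1].copy()
        hi = table.subjects.iloc[:1].copy()
        lo["pma_scan"], hi["pma_scan"] = pma.mean() - pma.std(), pma.mean() + pma.std()
        m_lo = predict(model, lo).mean[0, 0, 0]
        m_hi = predict(model, hi).mean[0, 0, 0]
        slope = (m_hi - m_lo) / 2.0
        assert abs(slope - 2.0) < 0.1

    def test_constant_output_noise_only_fallback(self):
        pma = np.linspace(38, 44, 20)
        table = make_single_cell_table(np.full(20, 3.7), pma)
        model = fit_normative_model(table, restarts=2, seed=1)
        pred = predict(model, table.subjects)
        assert np.allclose(pred.mean, 3.7)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        pma = rng.uniform(37, 45, 30)
        y = 0.1 * pma + rng.normal(0, 0.2, 30)
        table = make_single_cell_table(y, pma)
        m1 = fit_normative_model(table, restarts=3, seed=9)
        m2 = fit_normative_model(table, restarts=3, seed=9)
        assert np.array_equal(m1.params, m2.params)

    def test_optimum_beats_every_initialization(self):
        # log marginal likelihood at the optimum dominates the random starts
        from corticonorm.normative import _fit_cell, _initial_points

        rng = np.random.default_rng(7)
        n = 50
        X = np.column_stack([rng.normal(0, 1, n), rng.integers(0, 2, n)])
        y = np.sin(X[:, 0]) + rng.normal(0, 0.3, n)
        y = (y - y.mean()) / y.std()
        d2 = ((X[:, None] - X[None]) ** 2).sum(-1)
        inits = _initial_points(4, rng)
        _, best_lml, init_nlls, ok = _fit_cell(y, d2, X @ X.T, inits)
        assert ok
        assert best_lml >= max(-nll for nll in init_nlls) - 1e-9

    def test_requires_minimum_training_size(self):
        table = make_single_cell_table(np.arange(5.0), np.linspace(38, 44, 5))
        with pytest.raises(ValueError, match="10 training"):
            fit_normative_model(table)


class TestPredict:
    def test_interpolates_noiseless_training_data(self):
        rng = np.random.default_rng(2)
        pma = rng.uniform(37, 45, 30)
        y = 0.05 * (pma - 40) + 1.1  # exact linear function, no noise
        table = make_single_cell_table(y, pma)
        model = fit_normative_model(table, restarts=2, seed=3)
        pred = predict(model, table.subjects)
        assert np.abs(pred.mean[:, 0, 0] - y).max() < 1e-6

    def test_linear_kernel_matches_bayesian_linear_regression(self):
        # closed-form conjugate oracle on 20 random small datasets
        result = gp_blr_agreement(seed=123, n_datasets=20)
        assert result["max_abs_diff"] < 1e-6

    def test_matches_sklearn_gp_at_fixed_hyperparameters(self):
        # independent route: sklearn's GP with the identical kernel
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import (
            RBF,
            ConstantKernel,
            DotProduct,
            WhiteKernel,
        )

        rng = np.random.default_rng(3)
        n = 40
        X = np.column_stack([rng.normal(0, 1, n), rng.integers(0, 2, n)])
        y = np.sin(X[:, 0]) + 0.5 * X[:, 1] + rng.normal(0, 0.2, n)
        rv, ls, lv, nv = 0.8, 1.3, 0.4, 0.05

        model = _linear_only_model(X, y, lv, nv)
        model.params[0, 0] = (rv, ls, lv, nv)
        Xs = np.column_stack([rng.normal(0, 1, 8), rng.integers(0, 2, 8)])
        subs = pd.DataFrame(
            {"subject_id": [f"t{i}" for i in range(8)],
             "pma_scan": Xs[:, 0], "sex": Xs[:, 1]}
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred = predict(model, subs)

        kernel = (
            ConstantKernel(rv, "fixed") * RBF(ls, "fixed")
            + ConstantKernel(lv, "fixed") * DotProduct(sigma_0=0.0,
                                                       sigma_0_bounds="fixed")
            + WhiteKernel(nv, "fixed")
        )
        gpr = GaussianProcessRegressor(kernel=kernel, alpha=1e-8, optimizer=None)
        gpr.fit(X, y)
        sk_mean, sk_std = gpr.predict(Xs, return_std=True)
        np.testing.assert_allclose(pred.mean[:, 0, 0], sk_mean, atol=1e-6)
        np.testing.assert_allclose(
            np.sqrt(pred.variance[:, 0, 0]), sk_std, atol=1e-6
        )

    def test_variance_at_least_noise_level(self, term_model):
        model, _, holdout = term_model
        pred = predict(model, holdout.subjects)
        noise_floor = model.params[:, :, 3] * model.y_sd**2
        assert (pred.variance >= noise_floor[None] - 1e-12).all()

    def test_empty_subject_list(self, term_model):
        model, _, _ = term_model
        pred = predict(model, pd.DataFrame(columns=["subject_id", "pma_scan", "sex"]))
        assert pred.mean.shape[0] == 0

    def test_extrapolation_warns(self, term_model):
        model, _, holdout = term_model
        far = holdout.subjects.copy()
        far["pma_scan"] = 50.0
        with pytest.warns(UserWarning, match="outside the training range"):
            predict(model, far)


class TestEvaluateMae:
    def test_single_subject_exact(self, term_model):
        model, _, holdout = term_model
        one = holdout.subset(holdout.subject_ids[:1])
        pred = predict(model, one.subjects)
        mae = evaluate_mae(model, one)
        np.testing.assert_allclose(
            mae, np.abs(one.values - pred.mean)[0], atol=1e-12
        )

    def test_pure_noise_mae_approaches_half_normal_mean(self):
        # for N(0, s^2) residuals, E|e| = s * sqrt(2/pi)
        rng = np.random.default_rng(4)
        s = 0.3
        pma_tr = rng.uniform(37, 45, 100)
        table = make_single_cell_table(rng.normal(0, s, 100), pma_tr)
        model = fit_normative_model(table, restarts=2, seed=5)
        pma_ho = rng.uniform(37, 45, 500)
        hold = make_single_cell_table(rng.normal(0, s, 500), pma_ho)
        hold.subjects["subject_id"] = [f"h{i}" for i in range(500)]
        mae = evaluate_mae(model, hold)[0, 0]
        expected = s * np.sqrt(2 / np.pi)
        assert abs(mae - expected) / expected < 0.10

    def test_refuses_overlapping_subjects(self, term_model):
        model, train, _ = term_model
        with pytest.raises(ValueError, match="overlap"):
            evaluate_mae(model, train)
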