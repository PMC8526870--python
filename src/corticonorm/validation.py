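"""Self-validation experiments on synthetic cohorts with known truth.

Each function builds a cohort from the generator, runs the corresponding
pipeline stage end to end, and measures a calibration or recovery property
against the generative ground truth: pooled Z calibration of the normative
model, agreement of the linear-kernel GP with closed-form Bayesian linear
regression, family-wise error control of the max-statistic permutation test
under the global null, recovery of injected extreme deviations and group
effects, the bias-correction inversion identity, and the null behaviour of
the group x PMA interaction test.

These are the quantitative guarantees the synthetic study design can make;
they are exercised by the test suite and recomputed from scratch by
``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from .ageprediction import (
    AgePredConfig,
    evaluate_age_model,
    fit_bias_correction,
    train_age_model,
)
from .cohort import (
    METRICS,
    REGIONS,
    default_effect_config,
    generate_features,
    generate_parcellation,
    sample_demographics,
)
from .deviations import classify_extremes, compute_z_scores
from .normative import NormativeModel, fit_normative_model, predict, split_cohort
from .permutation import design_group, interaction_test, permutation_test


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


# ---------------------------------------------------------------------------
# Z calibration of the normative model
# ---------------------------------------------------------------------------

def z_calibration_experiment(
    seed: int = 0,
    n_train: int = 150,
    n_holdout: int = 50,
    parcels_per_hemisphere: int = 125,
    restarts: int = 2,
) -> dict:
    """Fit on synthetic term subjects, score held-out term subjects drawn
    from the same process, and pool Z over every (subject, parcel, metric).

    A calibrated normative model gives pooled mean ~0, variance ~1 and an
    |Z| > 3.1 rate near the two-sided normal tail 2*(1 - Phi(3.1)) = 0.00194.
    """
    s = _child_seeds(seed, 4)
    parcels = generate_parcellation(parcels_per_hemisphere, s[0])
    subjects = sample_demographics(n_train + n_holdout, 0, s[1])
    cfg = default_effect_config(seed=s[2], extreme_rate=0.0)
    table, _ = generate_features(subjects, parcels, cfg)
    ids = table.subject_ids
    train = table.subset(ids[:n_train])
    holdout = table.subset(ids[n_train:])
    model = fit_normative_model(train, restarts=restarts, seed=s[3])
    z = compute_z_scores(predict(model, holdout.subjects), holdout).z
    return {
        "z_mean": float(z.mean()),
        "z_var": float(z.var()),
        "extreme_rate": float((np.abs(z) > 3.1).mean()),
        "n_cells": int(z.size),
    }


# ---------------------------------------------------------------------------
# Linear-kernel GP vs closed-form Bayesian linear regression
# ---------------------------------------------------------------------------

def _linear_only_model(X, y, linear_variance, noise_variance) -> NormativeModel:
    n = X.shape[0]
    params = np.zeros((1, 1, 4))
    params[0, 0] = (0.0, 1.0, linear_variance, noise_variance)
    return NormativeModel(
        params=params,
        status=np.zeros((1, 1), dtype=int),
        log_marginal=np.zeros((1, 1)),
        x_train=X,
        y_train_std=y.reshape(n, 1, 1),
        y_mean=np.zeros((1, 1)),
        y_sd=np.ones((1, 1)),
        pma_mean=0.0,
        pma_sd=1.0,
        parcel_ids=np.array([0]),
        metrics=("FA",),
    )


def gp_blr_agreement(seed: int = 0, n_datasets: int = 20) -> dict:
    """Max |difference| between the linear-kernel GP posterior and the
    closed-form Bayesian linear regression predictive mean/variance.

    With kernel s_l^2 (x . x') the GP prior is y = w.x with w ~ N(0, s_l^2 I),
    so the predictive distribution has the conjugate closed form
    mean = x* S X'y / s_n^2, var = x* S x*' + s_n^2 with
    S = (X'X / s_n^2 + I / s_l^2)^{-1}.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    import pandas as pd

    for _ in range(n_datasets):
        n = int(rng.integers(8, 31))
        X = np.column_stack([rng.normal(0, 1, n), rng.integers(0, 2, n)])
        w = rng.normal(0, 1, 2)
        lv = float(rng.uniform(0.3, 3.0))
        nv = float(rng.uniform(0.05, 0.5))
        y = X @ w + rng.normal(0, np.sqrt(nv), n)

        model = _linear_only_model(X, y, lv, nv)
        n_test = 6
        Xs = np.column_stack(
            [rng.normal(0, 1, n_test), rng.integers(0, 2, n_test)]
        )
        test_subjects = pd.DataFrame(
            {
                "subject_id": [f"t{i}" for i in range(n_test)],
                "pma_scan": Xs[:, 0],
                "sex": Xs[:, 1],
            }
        )
        pred = predict(model, test_subjects)

        S = np.linalg.inv(X.T @ X / nv + np.eye(2) / lv)
        m_w = S @ X.T @ y / nv
        blr_mean = Xs @ m_w
        blr_var = np.einsum("ij,jk,ik->i", Xs, S, Xs) + nv

        worst = max(
            worst,
            float(np.abs(pred.mean[:, 0, 0] - blr_mean).max()),
            float(np.abs(pred.variance[:, 0, 0] - blr_var).max()),
        )
    return {"max_abs_diff": worst, "n_datasets": n_datasets}


# ---------------------------------------------------------------------------
# Family-wise error rate of the max-statistic permutation test
# ---------------------------------------------------------------------------

def fwer_experiment(
    seed: int = 0,
    n_replicates: int = 200,
    n_perm: int = 500,
    n_term: int = 28,
    n_preterm: int = 12,
    parcels_per_hemisphere: int = 10,
    alpha: float = 0.05,
) -> dict:
    """Family-wise rejection rate of the group contrast over replicate
    global-null cohorts (no group effect, no extremes; age and sex effects
    present and handled as nuisance)."""
    seeds = _child_seeds(seed, 3 * n_replicates + 1)
    parcels = generate_parcellation(parcels_per_hemisphere, seeds[-1])
    n_reject = 0
    for i in range(n_replicates):
        subjects = sample_demographics(n_term, n_preterm, seeds[3 * i])
        cfg = default_effect_config(
            seed=seeds[3 * i + 1], extreme_rate=0.0,
            preterm_effect={m: {r: 0.0 for r in REGIONS} for m in METRICS},
        )
        table, _ = generate_features(subjects, parcels, cfg)
        res = permutation_test(
            table, design_group(subjects), n_perm=n_perm,
            seed=seeds[3 * i + 2], alpha=alpha,
        )
        if res.significant.any():
            n_reject += 1
    return {
        "fwer": n_reject / n_replicates,
        "n_replicates": n_replicates,
        "n_perm": n_perm,
    }


# ---------------------------------------------------------------------------
# Recovery of injected effects
# ---------------------------------------------------------------------------

def extreme_recovery_experiment(
    seed: int = 0,
    n_term: int = 100,
    n_preterm: int = 40,
    parcels_per_hemisphere: int = 30,
    restarts: int = 2,
    magnitude_range: tuple[float, float] = (5.0, 6.0),
) -> dict:
    """Fraction of injected extreme offsets (>= 5 noise SD) flagged with the
    matching sign by the normative pipeline.

    Group effects are switched off so the only deviations are the injected
    ones; the normative model is trained on the term sample and the preterm
    sample is scored.
    """
    s = _child_seeds(seed, 4)
    parcels = generate_parcellation(parcels_per_hemisphere, s[0])
    subjects = sample_demographics(n_term, n_preterm, s[1])
    cfg = default_effect_config(
        seed=s[2],
        extreme_rate=1.0,
        extreme_magnitude_range=magnitude_range,
        preterm_effect={m: {r: 0.0 for r in REGIONS} for m in METRICS},
    )
    table, truth = generate_features(subjects, parcels, cfg)
    term_ids = subjects.loc[subjects["group"] == "term", "subject_id"]
    preterm_ids = subjects.loc[subjects["group"] == "preterm", "subject_id"]
    model = fit_normative_model(table.subset(term_ids), restarts=restarts, seed=s[3])
    scored = table.subset(preterm_ids)
    z = compute_z_scores(predict(model, scored.subjects), scored)
    mask = classify_extremes(z)

    pre_rows = subjects.index[subjects["group"] == "preterm"].to_numpy()
    truth_pre = truth.extreme_mask_true[pre_rows]
    injected = truth_pre != 0
    n_injected = int(injected.sum())
    n_recovered = int((mask.label[injected] == truth_pre[injected]).sum())
    return {
        "recovery_rate": n_recovered / n_injected if n_injected else float("nan"),
        "n_injected": n_injected,
    }


def group_effect_detection_experiment(
    seed: int = 0,
    n_term: int = 100,
    n_preterm: int = 40,
    parcels_per_hemisphere: int = 30,
    n_effect_parcels: int = 20,
    effect_size_sd: float = 1.5,
    n_perm: int = 1000,
    alpha: float = 0.05,
) -> dict:
    """Sensitivity and false-positive rate of the group permutation test for
    a known group shift of ``effect_size_sd`` noise SD injected into
    ``n_effect_parcels`` parcels of one metric (MD) for all preterm
    subjects."""
    s = _child_seeds(seed, 4)
    parcels = generate_parcellation(parcels_per_hemisphere, s[0])
    subjects = sample_demographics(n_term, n_preterm, s[1])
    cfg = default_effect_config(
        seed=s[2], extreme_rate=0.0,
        preterm_effect={m: {r: 0.0 for r in REGIONS} for m in METRICS},
    )
    table, _ = generate_features(subjects, parcels, cfg)

    rng = np.random.default_rng(s[3])
    j = METRICS.index("MD")
    effect_parcels = rng.choice(parcels.n_parcels, n_effect_parcels, replace=False)
    noise_sd = cfg.as_arrays(parcels.regions)["noise_sd"][:, j]
    pre_rows = subjects.index[subjects["group"] == "preterm"].to_numpy()
    for p in effect_parcels:
        table.values[pre_rows, p, j] += effect_size_sd * noise_sd[p]

    res = permutation_test(
        table, design_group(subjects), n_perm=n_perm, seed=s[3], alpha=alpha
    )
    sig_pos = res.significant_pos  # preterm > term direction
    effect_mask = np.zeros((parcels.n_parcels, len(METRICS)), dtype=bool)
    effect_mask[effect_parcels, j] = True
    sensitivity = float(sig_pos[effect_mask].mean())
    false_pos = float(res.significant[~effect_mask].mean())
    return {
        "sensitivity": sensitivity,
        "false_positive_rate": false_pos,
        "n_effect_parcels": n_effect_parcels,
    }


# ---------------------------------------------------------------------------
# Interaction test under equal slopes
# ---------------------------------------------------------------------------

def interaction_null_experiment(
    seed: int = 0,
    n_replicates: int = 20,
    n_term: int = 60,
    n_preterm: int = 30,
    parcels_per_hemisphere: int = 15,
    n_perm: int = 500,
    alpha: float = 0.05,
) -> dict:
    """Fraction of replicate cohorts with *zero* significant group x PMA
    interaction parcels when both groups share every age slope (the
    generator's slopes do not depend on group, so the interaction null holds
    by construction; group intercept shifts are present and are nuisance)."""
    seeds = _child_seeds(seed, 3 * n_replicates + 1)
    parcels = generate_parcellation(parcels_per_hemisphere, seeds[-1])
    clean = 0
    for i in range(n_replicates):
        subjects = sample_demographics(n_term, n_preterm, seeds[3 * i])
        cfg = default_effect_config(seed=seeds[3 * i + 1], extreme_rate=0.0)
        table, _ = generate_features(subjects, parcels, cfg)
        res = interaction_test(table, n_perm=n_perm, seed=seeds[3 * i + 2],
                               alpha=alpha)
        if not res.significant.any():
            clean += 1
    return {"clean_fraction": clean / n_replicates, "n_replicates": n_replicates}


# ---------------------------------------------------------------------------
# Age prediction: bias-correction identity and holdout performance
# ---------------------------------------------------------------------------

def age_prediction_experiment(
    seed: int = 0,
    n_term: int = 120,
    parcels_per_hemisphere: int = 20,
    n_estimators: int = 300,
) -> dict:
    """Train the random forest on a synthetic term cohort, fit the
    error-in-variables correction, and report (a) the algebraic identity
    that corrected training predictions regress on true age with slope 1 and
    intercept 0, and (b) corrected hold-out performance."""
    s = _child_seeds(seed, 5)
    parcels = generate_parcellation(parcels_per_hemisphere, s[0])
    subjects = sample_demographics(n_term, 0, s[1])
    cfg = default_effect_config(seed=s[2], extreme_rate=0.0)
    table, _ = generate_features(subjects, parcels, cfg)
    split = split_cohort(subjects, 0.25, s[3])
    train = table.subset(split.index[split == "train"])
    hold = table.subset(split.index[split == "holdout"])

    rf = train_age_model(train, AgePredConfig(n_estimators=n_estimators, seed=s[4]))
    true_train = train.subjects["pma_scan"].to_numpy(float)
    raw_train = rf.predict(train.flatten())
    correction = fit_bias_correction(raw_train, true_train)
    corrected_train = correction.apply(raw_train)
    slope, intercept = np.polyfit(true_train, corrected_train, 1)

    report = evaluate_age_model(rf, correction, hold,
                                train_subject_ids=train.subject_ids)
    return {
        "identity_slope": float(slope),
        "identity_intercept": float(intercept),
        "holdout_mae": report.mae,
        "holdout_spearman_rho": report.spearman_rho,
        "holdout_r_squared": report.r_squared,
        "n_train": len(train.subjects),
    }
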