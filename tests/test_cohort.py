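"""Synthetic cohort generator: determinism, invariants, effect injection."""

import numpy as np
import pandas as pd
import pytest

from corticonorm import (
    METRICS,
    REGIONS,
    default_effect_config,
    generate_features,
    generate_parcellation,
    sample_demographics,
)
from corticonorm.cohort import ConfigError, SubjectRecord


class TestParcellation:
    def test_study_size_has_286_parcels(self):
        parcels = generate_parcellation(143, seed=1)
        assert parcels.n_parcels == 286
        assert (parcels.table.groupby("hemisphere").size() == 143).all()

    def test_minimum_case_covers_all_regions_per_hemisphere(self):
        parcels = generate_parcellation(7, seed=1)
        assert parcels.n_parcels == 14
        for hemi in ("left", "right"):
            regions = set(parcels.table.loc[parcels.table.hemisphere == hemi, "region"])
            assert regions == set(REGIONS)

    def test_deterministic_given_seed(self):
        a = generate_parcellation(50, seed=1)
        b = generate_parcellation(50, seed=1)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_parcel_ids_unique_contiguous_and_on_unit_sphere(self):
        parcels = generate_parcellation(20, seed=3)
        assert np.array_equal(parcels.parcel_ids, np.arange(40))
        norms = np.linalg.norm(parcels.table[["x", "y", "z"]].to_numpy(), axis=1)
        assert np.allclose(norms, 1.0, atol=1e-12)

    def test_rejects_too_few_parcels(self):
        with pytest.raises(ValueError, match="per region"):
            generate_parcellation(6, seed=1)


class TestDemographics:
    def test_study_sample_sizes_and_ga_windows(self):
        subs = sample_demographics(259, 76, seed=7)
        assert len(subs) == 335
        term = subs[subs.group == "term"]
        pre = subs[subs.group == "preterm"]
        assert (term.ga_birth >= 37).all() and (term.ga_birth <= 42.14).all()
        assert (pre.ga_birth >= 23).all() and (pre.ga_birth < 37).all()

    def test_ga_bounds_hold_in_large_samples(self):
        # enumerate the empirical range over a large draw
        subs = sample_demographics(1000, 1000, seed=3)
        term_ga = subs.loc[subs.group == "term", "ga_birth"]
        assert term_ga.min() >= 37 and term_ga.max() <= 42.14

    def test_pma_window_and_birth_order(self):
        subs = sample_demographics(300, 100, seed=5)
        assert (subs.pma_scan >= 37).all() and (subs.pma_scan <= 45.14).all()
        assert (subs.pma_scan >= subs.ga_birth).all()

    def test_single_preterm_record(self):
        subs = sample_demographics(0, 1, seed=1)
        assert len(subs) == 1 and subs.group.iloc[0] == "preterm"

    def test_outcome_scores_plausible(self):
        subs = sample_demographics(500, 0, seed=9)
        for col in ("bsid_motor", "bsid_language", "bsid_cognitive"):
            assert subs[col].between(40, 160).all()
            assert abs(subs[col].mean() - 100) < 3

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            sample_demographics(-1, 5, seed=1)

    def test_subject_record_validates_group_consistency(self):
        with pytest.raises(ValueError):
            SubjectRecord("x", "term", ga_birth=35.0, pma_scan=40.0, sex=0)
        with pytest.raises(ValueError):
            SubjectRecord("x", "preterm", ga_birth=38.0, pma_scan=40.0, sex=0)


class TestGenerateFeatures:
    def test_degenerate_generator_returns_baseline(self, small_parcellation):
        subs = sample_demographics(5, 0, seed=1)
        cfg = default_effect_config(
            seed=1,
            extreme_rate=0.0,
            noise_sd={m: {r: 1e-9 for r in REGIONS} for m in METRICS},
            age_slope={m: {r: 0.0 for r in REGIONS} for m in METRICS},
            sex_effect={m: 0.0 for m in METRICS},
        )
        table, _ = generate_features(subs, small_parcellation, cfg)
        arrs = cfg.as_arrays(small_parcellation.regions)
        assert np.allclose(table.values, arrs["baseline"][None], atol=1e-6)

    def test_injected_offset_magnitude_is_exact(self, small_parcellation):
        # magnitude range collapsed to a point: differencing against a
        # generation that shares the same noise draw but injects nothing
        # isolates the offsets, which must be exactly 5 noise SD
        subs = sample_demographics(0, 10, seed=2)
        kw = dict(
            seed=3,
            extreme_magnitude_range=(5.0, 5.0),
            # small noise keeps every metric far from its bounds (no clipping)
            noise_sd={m: {r: 1e-3 for r in REGIONS} for m in METRICS},
            preterm_effect={m: {r: 0.0 for r in REGIONS} for m in METRICS},
        )
        with_ext, truth = generate_features(
            subs, small_parcellation, default_effect_config(extreme_rate=1.0, **kw)
        )
        without, _ = generate_features(
            subs, small_parcellation, default_effect_config(extreme_rate=0.0, **kw)
        )
        dev = (with_ext.values - without.values) / 1e-3
        hit = truth.extreme_mask_true != 0
        assert hit.any()
        np.testing.assert_allclose(np.abs(dev[hit]), 5.0, rtol=1e-9)
        assert np.array_equal(np.sign(dev[hit]), truth.extreme_mask_true[hit])
        assert np.allclose(dev[~hit], 0.0)

    def test_ground_truth_counts_match_injections(self, small_cohort):
        table, truth, _ = small_cohort
        assert truth.n_injected == np.count_nonzero(truth.extreme_mask_true)
        # extremes only injected for preterm subjects by default
        term_rows = table.subjects.index[table.subjects.group == "term"]
        assert not truth.extreme_mask_true[term_rows].any()

    def test_determinism(self, small_parcellation):
        subs = sample_demographics(20, 10, seed=4)
        cfg = default_effect_config(seed=5)
        t1, g1 = generate_features(subs, small_parcellation, cfg)
        t2, g2 = generate_features(subs, small_parcellation, cfg)
        assert np.array_equal(t1.values, t2.values)
        assert np.array_equal(g1.extreme_mask_true, g2.extreme_mask_true)

    def test_bounded_metrics_within_bounds(self, small_cohort):
        table, _, _ = small_cohort
        for m in ("FA", "ODI", "fICVF"):
            j = METRICS.index(m)
            assert table.values[:, :, j].min() >= 0
            assert table.values[:, :, j].max() <= 1
        for m in ("MD", "thickness", "SA"):
            j = METRICS.index(m)
            assert table.values[:, :, j].min() > 0

    def test_null_group_effect_gives_matched_group_means(self, small_parcellation):
        # with preterm effects and extremes off, group means per parcel agree
        # within sampling error in nearly all parcels
        rng_checks = []
        for seed in (10, 11, 12):
            subs = sample_demographics(250, 250, seed=seed)
            # age and sex effects zeroed too: raw group means are compared,
            # so covariate sampling noise must not masquerade as group shift
            cfg = default_effect_config(
                seed=seed,
                extreme_rate=0.0,
                preterm_effect={m: {r: 0.0 for r in REGIONS} for m in METRICS},
                age_slope={m: {r: 0.0 for r in REGIONS} for m in METRICS},
                sex_effect={m: 0.0 for m in METRICS},
            )
            table, _ = generate_features(subs, small_parcellation, cfg)
            term = table.values[(subs.group == "term").to_numpy()]
            pre = table.values[(subs.group == "preterm").to_numpy()]
            se = np.sqrt(
                term.var(axis=0, ddof=1) / term.shape[0]
                + pre.var(axis=0, ddof=1) / pre.shape[0]
            )
            zdiff = (term.mean(0) - pre.mean(0)) / se
            rng_checks.append((np.abs(zdiff) < 3).mean())
        assert np.mean(rng_checks) >= 0.99

    def test_noise_scaling_doubles_residual_sd(self, small_parcellation):
        subs = sample_demographics(500, 0, seed=6)
        kw = dict(
            extreme_rate=0.0,
            age_slope={m: {r: 0.0 for r in REGIONS} for m in METRICS},
            sex_effect={m: 0.0 for m in METRICS},
        )
        cfg1 = default_effect_config(seed=7, **kw)
        cfg2 = default_effect_config(
            seed=7,
            noise_sd={m: {r: 2 * cfg1.noise_sd[m][r] for r in REGIONS}
                      for m in METRICS},
            **kw,
        )
        t1, _ = generate_features(subs, small_parcellation, cfg1)
        t2, _ = generate_features(subs, small_parcellation, cfg2)
        j = METRICS.index("thickness")  # far from bounds, no clipping
        ratio = t2.values[:, :, j].std(0) / t1.values[:, :, j].std(0)
        assert np.allclose(ratio, 2.0, atol=0.25)

    def test_refuses_pma_outside_window(self, small_parcellation):
        subs = sample_demographics(5, 0, seed=8)
        subs.loc[0, "pma_scan"] = 50.0
        with pytest.raises(ValueError, match="PMA"):
            generate_features(subs, small_parcellation, default_effect_config())

    def test_incomplete_config_rejected(self):
        cfg = default_effect_config()
        broken = dict(cfg.baseline)
        broken.pop("FA")
        with pytest.raises(ConfigError, match="FA"):
            default_effect_config(baseline=broken)
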