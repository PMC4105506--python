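"""Calibration and sampling behavior of the synthetic-cohort generator."""

import numpy as np
import pandas as pd
import pytest

from bsisurv import (
    CohortConfig,
    REGIONS,
    calibrate_from_summary,
    default_config,
    default_profiles,
    generate_cohort,
    sample_regional_bsi,
    sample_survival,
)
from bsisurv.cox import fit_cox
from bsisurv.synthetic import TABLE1_SUMMARY, RegionProfile, nearest_psd_correlation


class TestCalibration:
    def test_costae_row_moment_matching(self):
        profiles = {p.name: p for p in calibrate_from_summary(TABLE1_SUMMARY)}
        costae = profiles["Costae"]
        assert costae.zero_fraction == pytest.approx(0.5209)
        assert costae.positive_mean == pytest.approx(0.30 / 0.4791, abs=1e-3)

    def test_degenerate_all_zero_profile(self):
        prof = RegionProfile(name="Skull", zero_fraction=1.0, mean=0.0, median=0.0, sd=0.0)
        assert prof.positive_quantile(np.array([0.5]))[0] == 0.0

    def test_inconsistent_all_zero_with_positive_mean_rejected(self):
        with pytest.raises(ValueError):
            RegionProfile(name="Skull", zero_fraction=1.0, mean=0.3, median=0.0, sd=0.1)

    def test_majority_zero_forces_zero_median(self):
        with pytest.raises(ValueError):
            RegionProfile(name="Skull", zero_fraction=0.8, mean=0.1, median=0.05, sd=0.2)

    def test_missing_region_label_rejected(self):
        with pytest.raises(ValueError, match="Pelvis"):
            calibrate_from_summary(TABLE1_SUMMARY[TABLE1_SUMMARY.region != "Pelvis"])

    def test_pelvis_mixture_moments_by_monte_carlo(self):
        # moment-matched log-normal positive part must reproduce the
        # mixture mean and sd of the Pelvis row at Monte-Carlo scale
        prof = {p.name: p for p in default_profiles()}["Pelvis"]
        rng = np.random.default_rng(0)
        n = 1_000_000
        x = np.where(
            rng.random(n) < prof.zero_fraction,
            0.0,
            rng.lognormal(prof.ln_mu, prof.ln_sigma, n),
        )
        assert x.mean() == pytest.approx(0.78, rel=0.01)
        assert x.std(ddof=1) == pytest.approx(1.23, rel=0.01)


class TestRegionalSampling:
    def test_all_zero_fractions_give_zero_matrix(self):
        profiles = [
            RegionProfile(name=r, zero_fraction=1.0, mean=0.0, median=0.0, sd=0.0)
            for r in REGIONS
        ]
        cfg = default_config(n=50, region_profiles=profiles)
        X = sample_regional_bsi(cfg, np.random.default_rng(0))
        assert np.all(X == 0.0)

    def test_identity_copula_gives_uncorrelated_columns(self):
        cfg = default_config(n=20_000, copula_correlation=np.eye(12))
        X = sample_regional_bsi(cfg, np.random.default_rng(1))
        for a, b in [(0, 1), (5, 10), (6, 2)]:
            m = (X[:, a] > 0) & (X[:, b] > 0)
            # 4 Monte-Carlo standard errors at the pair's subset size
            assert abs(np.corrcoef(X[m, a], X[m, b])[0, 1]) < 4.0 / np.sqrt(m.sum())

    def test_copula_rho_survives_zero_inflation_attenuated(self):
        C = np.eye(12)
        i, j = REGIONS.index("Th_Spine"), REGIONS.index("L_Spine")
        C[i, j] = C[j, i] = 0.8
        cfg = default_config(n=20_000, copula_correlation=C)
        X = sample_regional_bsi(cfg, np.random.default_rng(2))
        m = (X[:, i] > 0) & (X[:, j] > 0)
        assert np.corrcoef(X[m, i], X[m, j])[0, 1] > 0.5

    def test_non_psd_copula_rejected(self):
        C = np.eye(12)
        C[0, 1] = C[1, 0] = 0.9
        C[0, 2] = C[2, 0] = 0.9
        C[1, 2] = C[2, 1] = -0.9
        with pytest.raises(ValueError, match="PSD"):
            default_config(n=100, copula_correlation=C)

    def test_nearest_psd_projection_fixes_it(self):
        C = np.eye(12)
        C[0, 1] = C[1, 0] = 0.9
        C[0, 2] = C[2, 0] = 0.9
        C[1, 2] = C[2, 1] = -0.9
        fixed = nearest_psd_correlation(C)
        assert np.linalg.eigvalsh(fixed).min() >= -1e-10
        assert np.diag(fixed) == pytest.approx(np.ones(12))

    def test_marginal_calibration_within_monte_carlo_error(self):
        cfg = default_config(n=100_000, seed=9)
        X = sample_regional_bsi(cfg, np.random.default_rng(9))
        for jdx, prof in enumerate(cfg.region_profiles):
            zf_emp = np.mean(X[:, jdx] == 0)
            se = np.sqrt(prof.zero_fraction * (1 - prof.zero_fraction) / cfg.n)
            assert abs(zf_emp - prof.zero_fraction) < 3 * se + 1e-4
            mean_se = prof.sd / np.sqrt(cfg.n)
            assert abs(X[:, jdx].mean() - prof.mean) < 3 * mean_se + 1e-3


class TestSurvivalSampling:
    def test_null_betas_refit_near_zero(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((10_000, 1))
        t, e = sample_survival(default_config(n=10_000), X, rng, betas=np.array([0.0]))
        assert abs(fit_cox(X, t, e, normalize=False).coefficients[0]) < 0.05

    def test_beta_recovery(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((10_000, 1))
        t, e = sample_survival(default_config(n=10_000), X, rng, betas=np.array([0.5]))
        assert 0.45 <= fit_cox(X, t, e, normalize=False).coefficients[0] <= 0.55

    def test_censoring_tuned_to_target(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((10_000, 1))
        t, e = sample_survival(default_config(n=10_000), X, rng, betas=np.array([0.3]))
        assert np.mean(e == 0) == pytest.approx(0.32, abs=0.02)

    def test_nonfinite_linear_predictor_rejected(self):
        rng = np.random.default_rng(6)
        X = np.array([[np.inf], [1.0], [2.0]])
        with pytest.raises(ValueError, match="linear predictor"):
            sample_survival(default_config(n=3), X, rng, betas=np.array([1.0]))


class TestGenerateCohort:
    def test_deterministic_given_seed_distinct_across_seeds(self):
        a = generate_cohort(default_config(n=120, seed=1))
        b = generate_cohort(default_config(n=120, seed=1))
        c = generate_cohort(default_config(n=120, seed=2))
        assert np.array_equal(a.regional, b.regional)
        assert np.array_equal(a.time, b.time)
        assert not np.array_equal(a.time, c.time)

    def test_reference_scale_zero_fractions(self):
        coh = generate_cohort(default_config(n=1013, seed=13))
        for jdx, row in TABLE1_SUMMARY.iterrows():
            emp = np.mean(coh.regional[:, jdx] == 0) * 100
            assert abs(emp - row.pct_zeros) < 4.0

    def test_age_independent_of_regional_burden(self):
        coh = generate_cohort(default_config(n=10_000, seed=14))
        for j in range(12):
            assert abs(np.corrcoef(coh.age, coh.regional[:, j])[0, 1]) <= 0.05

    def test_lesions_zero_when_burden_zero(self):
        coh = generate_cohort(default_config(n=2000, seed=15))
        zero_burden = coh.total_bsi == 0
        if zero_burden.any():
            assert np.all(coh.lesions[zero_burden] == 0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CohortConfig(n=1)
        with pytest.raises(ValueError):
            CohortConfig(n=10, censoring_window=0.0)

    def test_proportional_hazards_structure_recoverable(self):
        # Cox on generated cohorts recovers the true log hazard ratios
        hits = total = 0
        for seed in range(10):
            cfg = default_config(n=4000, seed=seed)
            coh = generate_cohort(cfg)
            X = np.column_stack([coh.age, coh.total_bsi])
            fit = fit_cox(X, coh.time, coh.event, normalize=False)
            true = cfg.beta_vector
            hits += int(np.sum(np.abs(fit.coefficients - true) <= 2 * fit.se))
            total += true.size
        assert hits / total >= 0.85  # nominal 2-SE coverage ~0.95
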