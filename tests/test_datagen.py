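"""Synthetic-cohort generator: marginals, latent structure, censoring, MCAR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cd4joint as cj
from cd4joint.datagen import (
    apply_mcar,
    generate_covariates,
    generate_latent_effects,
    generate_longitudinal,
    generate_survival,
    truncate_longitudinal,
)
from cd4joint.params import TrueParameters


def null_params(**over):
    base = dict(
        beta1={"intercept": 0.0},
        beta2={},
        Sigma_nu=np.zeros((2, 2)),
        sigma_b2=0.0,
        sigma_nu2=0.0,
        tau=(0.0, 0.0),
        tau_b=0.0,
        rho=1.0,
        phi=1.0,
        b_scale=0.0,
    )
    base.update(over)
    return TrueParameters(**base)


class TestCovariates:
    def test_female_fraction_within_binomial_bounds(self):
        cov = generate_covariates(792, seed=3)
        p = 0.506
        half = 2.576 * np.sqrt(p * (1 - p) / 792)  # 99% binomial bounds
        assert abs((cov["sex"] == "female").mean() - p) < half

    def test_degenerate_marginal_is_point_mass(self):
        cov = generate_covariates(1, marginals={"residence": {"rural": 1.0}}, seed=0)
        assert cov.loc[0, "residence"] == "rural"

    def test_law_of_large_numbers_rural(self):
        # oracle: direct counting against the requested frequency
        cov = generate_covariates(100_000, seed=5)
        assert abs((cov["residence"] == "rural").mean() - 0.409) < 0.005

    def test_exact_allocation_matches_largest_remainder(self):
        cov = generate_covariates(792, seed=1, exact=True)
        assert (cov["sex"] == "female").sum() == 401
        assert (cov["residence"] == "rural").sum() == 324
        assert (cov["adherence"] == "good").sum() == 540
        assert (cov["disclosure"] == "yes").sum() == 575

    def test_continuous_marginals_and_age_floor(self):
        cov = generate_covariates(5000, seed=2)
        assert cov["age"].min() >= 18
        assert abs(np.median(cov["baseline_cd4"]) - 150) < 10
        assert abs(np.median(cov["weight"]) - 62) < 3

    def test_non_normalised_marginals_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            generate_covariates(10, marginals={"sex": {"male": 0.6, "female": 0.6}})

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            generate_covariates(10, marginals={"species": {"a": 1.0}})

    def test_seed_determinism(self):
        a = generate_covariates(50, seed=9)
        b = generate_covariates(50, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestLatentEffects:
    def test_zero_dispersion_variance_degenerates(self, preset):
        from dataclasses import replace

        p = replace(preset, sigma_b2=0.0)
        eff = generate_latent_effects(100, p, seed=1)
        assert np.all(eff["log_b"] == 0.0)

    def test_sample_correlation_matches_closed_form(self):
        Sigma = np.array([[0.88, -0.054], [-0.054, 0.021]])
        p = null_params(Sigma_nu=Sigma, sigma_b2=0.1, sigma_nu2=0.1)
        eff = generate_latent_effects(50_000, p, seed=4)
        want = -0.054 / np.sqrt(0.88 * 0.021)
        got = np.corrcoef(eff["nu0"], eff["nu1"])[0, 1]
        assert abs(got - want) < 0.02

    def test_variance_components_recovered(self, preset):
        eff = generate_latent_effects(50_000, preset, seed=8)
        assert np.isclose(eff["log_b"].var(), preset.sigma_b2, rtol=0.05)
        assert np.isclose(eff["frailty"].var(), preset.sigma_nu2, rtol=0.05)

    def test_non_psd_sigma_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            TrueParameters(beta1={}, beta2={}, Sigma_nu=np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_seed_determinism_bitwise(self, preset):
        a = generate_latent_effects(20, preset, seed=3)
        b = generate_latent_effects(20, preset, seed=3)
        assert (a.to_numpy() == b.to_numpy()).all()


class TestLongitudinal:
    def test_all_variances_zero_gives_plain_poisson(self):
        # beta1 = (log 16, 0...) with no heterogeneity: counts ~ Poisson(16)
        p = null_params(beta1={"intercept": np.log(16.0)})
        cov = generate_covariates(3000, seed=1)
        eff = generate_latent_effects(3000, p, seed=2)
        long = generate_longitudinal(cov, eff, p, seed=3)
        y = long["cd4_change"].dropna()
        assert abs(y.mean() - 16.0) < 0.1
        assert abs(y.var() / y.mean() - 1.0) < 0.05

    def test_unit_mean_poisson_limit(self):
        p = null_params()
        cov = generate_covariates(4000, seed=1)
        eff = generate_latent_effects(4000, p, seed=2)
        long = generate_longitudinal(cov, eff, p, seed=3)
        y = long["cd4_change"].dropna()
        assert abs(y.mean() - 1.0) < 0.05
        assert abs(y.var() - 1.0) < 0.1

    def test_lognormal_dispersion_overdisperses_every_visit(self):
        # oracle: Poisson-log-normal variance mu + mu^2(e^s2 - 1) > mu
        p = null_params(beta1={"intercept": np.log(16.0)}, sigma_b2=0.5, b_scale=1.0)
        cov = generate_covariates(5000, seed=1)
        eff = generate_latent_effects(5000, p, seed=2)
        long = generate_longitudinal(cov, eff, p, seed=3)
        prof = cj.mean_variance_profile(long)
        assert prof["overdispersed"].all()

    def test_change_consistency_with_counts(self, small_cohort):
        full = small_cohort.longitudinal
        obs = full[full["cd4_change"].notna() & full["observed"]]
        # counts are the cumulative sum of changes on top of the reference
        derived = cj.compute_cd4_change(full)
        for pid, series in list(derived.items())[:20]:
            for j, ch in series.items():
                row = full[(full.patient_id == pid) & (full.visit_index == j)]
                if row["observed"].iloc[0] and not np.isnan(row["cd4_change"].iloc[0]):
                    assert ch == row["cd4_change"].iloc[0]

    def test_schedule_must_increase(self, preset):
        cov = generate_covariates(5, seed=1)
        eff = generate_latent_effects(5, preset, seed=1)
        with pytest.raises(ValueError, match="increasing"):
            generate_longitudinal(cov, eff, preset, schedule=np.array([3.0, 2.0]))


class TestSurvival:
    def test_unit_exponential_special_case(self):
        p = null_params()
        cov = generate_covariates(20_000, seed=1)
        eff = generate_latent_effects(20_000, p, seed=2)
        surv = generate_survival(cov, eff, p, max_followups=10_000, seed=3)
        assert abs(surv["time"].mean() - 1.0) < 0.02

    def test_weibull_closed_form_survival(self):
        # S(t) = exp(-phi t^rho) with a null linear predictor
        p = null_params(rho=0.763, phi=0.5)
        cov = generate_covariates(20_000, seed=1)
        eff = generate_latent_effects(20_000, p, seed=2)
        surv = generate_survival(cov, eff, p, max_followups=10_000, seed=3)
        for t0 in (0.5, 1.0, 2.0, 5.0):
            emp = (surv["time"] > t0).mean()
            assert abs(emp - np.exp(-0.5 * t0**0.763)) < 0.01

    def test_decreasing_hazard_for_shape_below_one(self):
        p = null_params(rho=0.763)
        cov = generate_covariates(20_000, seed=1)
        eff = generate_latent_effects(20_000, p, seed=2)
        surv = generate_survival(cov, eff, p, max_followups=10_000, seed=3)
        from lifelines import NelsonAalenFitter

        naf = NelsonAalenFitter()
        naf.fit(surv["time"], surv["event"])
        grid = np.array([0.5, 1.5, 3.0, 6.0])
        H = naf.cumulative_hazard_at_times(grid).to_numpy()
        increments = np.diff(H) / np.diff(grid)  # average hazard per interval
        assert np.all(np.diff(increments) < 0)

    def test_proportional_hazards_log_hr(self):
        # doubling one binary coefficient by delta shifts the KM log-HR by ~delta
        delta = 0.7
        p = null_params(beta2={"female": delta})
        cov = generate_covariates(20_000, seed=1)
        eff = generate_latent_effects(20_000, p, seed=2)
        surv = generate_survival(cov, eff, p, max_followups=10_000, seed=3)
        fit = cj.fit_cox(surv, cov, ["female"])
        assert abs(fit.coef.loc["female", "estimate"] - delta) < 0.05

    def test_administrative_censoring(self, preset):
        cov = generate_covariates(500, seed=1)
        eff = generate_latent_effects(500, preset, seed=2)
        surv = generate_survival(cov, eff, preset, max_followups=20, seed=3)
        censored = surv[surv["event"] == 0]
        assert (censored["time"] == 20).all()
        assert (surv["time"] > 0).all()

    def test_invalid_max_followups(self, preset):
        cov = generate_covariates(5, seed=1)
        eff = generate_latent_effects(5, preset, seed=2)
        with pytest.raises(ValueError):
            generate_survival(cov, eff, preset, max_followups=0, seed=3)


class TestMcarAndBookkeeping:
    def test_zero_probability_identity(self, small_cohort):
        out = apply_mcar(small_cohort.longitudinal, 0.0, seed=1)
        pd.testing.assert_frame_equal(out, small_cohort.longitudinal)

    def test_missing_fraction_binomial(self, preset):
        cov = generate_covariates(5000, seed=1)
        eff = generate_latent_effects(5000, preset, seed=2)
        long = generate_longitudinal(cov, eff, preset, seed=3)
        out = apply_mcar(long, 0.1, seed=4)
        eligible = out[out["visit_index"] > 1]
        frac = 1.0 - eligible["observed"].mean()
        assert abs(frac - 0.1) < 0.005

    def test_baseline_never_removed(self, small_cohort):
        base = small_cohort.longitudinal[small_cohort.longitudinal["visit_index"] == 1]
        assert base["observed"].all()

    def test_invalid_probability(self, small_cohort):
        with pytest.raises(ValueError):
            apply_mcar(small_cohort.longitudinal, 1.0)

    def test_censoring_bookkeeping(self, preset):
        """Records per patient = scheduled visits not after t_i, pre-MCAR."""
        cov = generate_covariates(200, seed=1)
        eff = generate_latent_effects(200, preset, seed=2)
        long = generate_longitudinal(cov, eff, preset, seed=3)
        surv = generate_survival(cov, eff, preset, max_followups=20, seed=4)
        trunc = truncate_longitudinal(long, surv)
        counts = trunc.groupby("patient_id").size()
        for _, row in surv.iterrows():
            expected = int(np.floor(min(row["time"], 20)))
            assert counts.get(row["patient_id"], 0) == expected

    def test_pipeline_determinism(self, preset):
        a = cj.simulate_cohort(60, params=preset, seed=5)
        b = cj.simulate_cohort(60, params=preset, seed=5)
        pd.testing.assert_frame_equal(a.longitudinal, b.longitudinal)
        pd.testing.assert_frame_equal(a.survival, b.survival)


def test_cohort_roundtrip(tmp_path, small_cohort):
    cj.write_cohort(small_cohort, tmp_path)
    cov, long, surv = cj.read_cohort(tmp_path)
    assert len(cov) == len(small_cohort.covariates)
    assert long["observed"].dtype == bool
    missing = long[~long["observed"]]
    assert missing["cd4_count"].isna().all()
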