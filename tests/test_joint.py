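"""Joint model: likelihood identities, sampler correctness, DIC, hazard ratios."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import cd4joint as cj
from cd4joint.joint import (
    JointModelSpec,
    McmcSettings,
    compute_dic,
    gibbs_variance,
    hazard_ratio_table,
    joint_log_likelihood,
    percent_change,
    prepare_data,
    run_ladder,
    run_mcmc,
)
from cd4joint.likelihoods import mvn2_loglik, normal_loglik, pln_marginal_loglik, weibull_loglik

LT = ["intercept", "age", "female", "time"]
ST = ["intercept", "age", "female"]


@pytest.fixture(scope="module")
def model_data(small_cohort):
    return prepare_data(
        small_cohort.longitudinal, small_cohort.survival, small_cohort.covariates, LT, ST
    )


class TestJointLikelihood:
    def test_separability_at_zero_loadings(self, small_cohort, model_data, preset):
        """With all loadings and the frailty off, the joint log-likelihood is
        exactly the sum of the separate submodule likelihoods."""
        from dataclasses import replace

        p = replace(preset, tau=(0.0, 0.0), tau_b=0.0)
        p = p.subset(LT + ST)
        eff = small_cohort.effects.copy()
        eff["frailty"] = 0.0
        total = joint_log_likelihood(p, eff, model_data)

        d = model_data
        beta1 = np.array([p.beta1[t] for t in d.long_terms])
        eta1 = d.X1 @ beta1 + eff["nu0"].to_numpy()[d.pat] + eff["nu1"].to_numpy()[d.pat] * d.tstd
        long_part = pln_marginal_loglik(d.y, eta1, np.exp(eff["log_b"].to_numpy())[d.pat])
        long_part += mvn2_loglik(eff["nu0"].to_numpy(), eff["nu1"].to_numpy(), p.Sigma_nu)
        long_part += normal_loglik(eff["log_b"].to_numpy(), p.sigma_b2)

        beta2 = np.array([p.beta2[t] for t in d.surv_terms])
        surv_part = weibull_loglik(d.t, d.delta, d.X2 @ beta2, p.rho, p.phi)
        surv_part += normal_loglik(eff["frailty"].to_numpy(), p.sigma_nu2)
        assert abs(total - (long_part + surv_part)) < 1e-10

    def test_single_patient_hand_oracle(self):
        """One patient, one visit: quadrature against scipy.integrate."""
        cov = pd.DataFrame(
            {"patient_id": [1], "sex": ["female"], "age": [30.0], "weight": [60.0],
             "baseline_cd4": [150.0], "residence": ["urban"], "marital": ["with_partner"],
             "education": ["primary"], "income": ["low"], "who_stage": ["stage2"],
             "cellphone": ["yes"], "disclosure": ["yes"], "adherence": ["good"]}
        )
        long = pd.DataFrame(
            {"patient_id": [1, 1], "visit_index": [1, 2], "visit_time": [1.0, 2.0],
             "cd4_count": [150, 157], "cd4_change": [np.nan, 7.0], "observed": [True, True]}
        )
        surv = pd.DataFrame({"patient_id": [1], "time": [4.0], "event": [1]})
        d = prepare_data(long, surv, cov, ["intercept"], ["intercept"])
        p = cj.TrueParameters(
            beta1={"intercept": 2.0}, beta2={"intercept": -1.0},
            Sigma_nu=np.array([[0.5, 0.0], [0.0, 0.1]]),
            sigma_b2=0.3, sigma_nu2=0.2, tau=(-0.5, 0.3), tau_b=0.1, rho=0.8,
        )
        lat = pd.DataFrame({"nu0": [0.4], "nu1": [-0.1], "log_b": [0.2], "frailty": [0.15]})
        got = joint_log_likelihood(p, lat, d)

        # hand expansion ------------------------------------------------
        b = np.exp(0.2)
        eta1 = 2.0 + 0.4 + (-0.1) * 0.0  # visit 2 -> coded time 0
        integrand = lambda e: stats.poisson.pmf(7, np.exp(eta1 + e)) * stats.norm.pdf(e, 0, np.sqrt(b))
        long_part = np.log(integrate.quad(integrand, -12, 12, limit=300)[0])
        w2 = -0.5 * 0.4 + 0.3 * (-0.1) + 0.1 * 0.2 + 0.15
        eta2 = -1.0 + w2
        h = np.log(0.8) + (0.8 - 1) * np.log(4.0) + eta2
        surv_part = h - 4.0**0.8 * np.exp(eta2)
        prior = (
            stats.norm.logpdf(0.4, 0, np.sqrt(0.5))
            + stats.norm.logpdf(-0.1, 0, np.sqrt(0.1))
            + stats.norm.logpdf(0.2, 0, np.sqrt(0.3))
            + stats.norm.logpdf(0.15, 0, np.sqrt(0.2))
        )
        assert abs(got - (long_part + surv_part + prior)) < 1e-7

    def test_loading_perturbation_isolated_to_survival(self, small_cohort, model_data, preset):
        from dataclasses import replace

        p = preset.subset(LT + ST)
        _, parts = joint_log_likelihood(p, small_cohort.effects, model_data, return_parts=True)
        p2 = replace(p, tau=(p.tau[0], p.tau[1] + 0.5))
        _, parts2 = joint_log_likelihood(p2, small_cohort.effects, model_data, return_parts=True)
        assert parts["longitudinal"] == parts2["longitudinal"]
        assert parts["latent_priors"] == parts2["latent_priors"]
        assert parts["survival"] != parts2["survival"]


class TestSamplerMechanics:
    def test_conjugate_variance_update_moments(self, rng):
        """Gibbs draw matches the closed-form inverse-gamma posterior."""
        x = rng.normal(0.0, np.sqrt(0.4), size=200)
        a0, b0 = 2.0, 0.2
        a = a0 + 100.0
        b = b0 + 0.5 * np.sum(x**2)
        want_mean = b / (a - 1)
        want_var = b**2 / ((a - 1) ** 2 * (a - 2))
        draws = np.array([gibbs_variance(rng, x, a0, b0) for _ in range(20000)])
        assert abs(draws.mean() - want_mean) < 4 * np.sqrt(want_var / 20000) + 1e-3
        assert abs(draws.var() - want_var) < 0.2 * want_var

    def test_same_seed_identical_draws(self, small_cohort):
        spec = JointModelSpec(longitudinal_terms=LT, survival_terms=ST)
        settings = McmcSettings(chains=1, iterations=120, burn=60, thin=1, seed=5,
                                adapt_interval=20)
        a = run_mcmc(small_cohort.longitudinal, small_cohort.survival,
                     small_cohort.covariates, spec, settings)
        b = run_mcmc(small_cohort.longitudinal, small_cohort.survival,
                     small_cohort.covariates, spec, settings)
        for k in a.draws:
            np.testing.assert_array_equal(a.draws[k], b.draws[k])

    def test_invalid_settings(self):
        with pytest.raises(ValueError):
            McmcSettings(iterations=100, burn=100)
        with pytest.raises(ValueError):
            McmcSettings(on_nonconvergence="explode")
        with pytest.raises(ValueError):
            JointModelSpec(ladder_level="rung_99")


class TestDic:
    def test_point_mass_posterior_gives_zero_pd(self, small_cohort):
        spec = JointModelSpec(longitudinal_terms=LT, survival_terms=ST)
        settings = McmcSettings(chains=1, iterations=60, burn=30, thin=1, seed=5,
                                adapt_interval=20)
        res = run_mcmc(small_cohort.longitudinal, small_cohort.survival,
                       small_cohort.covariates, spec, settings)
        # collapse every draw to its posterior mean -> degenerate posterior
        for k in res.draws:
            res.draws[k] = np.full_like(res.draws[k], res.draws[k].mean())
        for k in res.latent_draws:
            m = res.latent_draws[k].mean(axis=(0, 1))
            res.latent_draws[k] = np.broadcast_to(
                m, res.latent_draws[k].shape
            ).copy()
        dic = compute_dic(res)
        assert abs(dic.p_d) < 1e-6
        assert np.isclose(dic.dic, dic.dhat)

    def test_noise_covariate_does_not_improve_dic(self, medium_cohort, fast_settings):
        """Adding a pure-noise covariate should not lower DIC on average."""
        rng = np.random.default_rng(3)
        cov = medium_cohort.covariates.copy()
        spec0 = JointModelSpec(longitudinal_terms=LT, survival_terms=ST)
        res0 = run_mcmc(medium_cohort.longitudinal, medium_cohort.survival, cov,
                        spec0, fast_settings)
        # register a noise column as a design term for this test
        from cd4joint import design

        cov["noise"] = rng.standard_normal(len(cov))
        design.TERM_BUILDERS["noise"] = lambda df: df["noise"].to_numpy(float)
        try:
            spec1 = JointModelSpec(longitudinal_terms=LT + ["noise"], survival_terms=ST)
            res1 = run_mcmc(medium_cohort.longitudinal, medium_cohort.survival, cov,
                            spec1, fast_settings)
        finally:
            del design.TERM_BUILDERS["noise"]
        assert res1.dic.dic > res0.dic.dic - 30.0  # no systematic improvement


class TestLadder:
    def test_single_rung_report(self, small_cohort, fast_settings):
        table = run_ladder(
            small_cohort.longitudinal, small_cohort.survival, small_cohort.covariates,
            LT, ST, fast_settings, levels=("random_intercept",),
        )
        assert len(table) == 1
        assert table["selected"].iloc[0]

    def test_full_preset_selects_top_rung(self, medium_cohort, fast_settings):
        table = run_ladder(
            medium_cohort.longitudinal, medium_cohort.survival, medium_cohort.covariates,
            LT, ST, fast_settings,
        )
        sel = table.loc[table["selected"], "ladder_level"].iloc[0]
        assert sel == "intercept_slope_frailty"


class TestHazardRatios:
    def _result_with_draws(self, small_cohort, draws):
        spec = JointModelSpec(longitudinal_terms=LT, survival_terms=ST)
        settings = McmcSettings(chains=1, iterations=60, burn=30, thin=1, seed=5,
                                adapt_interval=20)
        res = run_mcmc(small_cohort.longitudinal, small_cohort.survival,
                       small_cohort.covariates, spec, settings)
        res.draws = draws
        return res

    def test_null_effect_unit_hr(self, small_cohort):
        res = self._result_with_draws(
            small_cohort, {"beta2:age": np.zeros((1, 200))}
        )
        row = hazard_ratio_table(res).loc["age"]
        assert row["hr"] == 1.0 and row["hr_q2.5"] == 1.0 and row["hr_q97.5"] == 1.0

    def test_small_positive_coefficient(self, small_cohort, rng):
        draws = {"beta2:time": 0.021 + 1e-6 * rng.standard_normal((1, 500))}
        row = hazard_ratio_table(self._result_with_draws(small_cohort, draws)).loc["time"]
        assert abs(row["hr"] - np.exp(0.021)) < 1e-4

    def test_quantile_equivariance(self, small_cohort, rng):
        """Interval endpoints = exp of the coefficient interval endpoints."""
        coef = rng.normal(0.3, 0.2, size=(1, 4000))
        row = hazard_ratio_table(
            self._result_with_draws(small_cohort, {"beta2:female": coef})
        ).loc["female"]
        lo, hi = np.quantile(coef, [0.025, 0.975])
        assert np.isclose(row["hr_q2.5"], np.exp(lo))
        assert np.isclose(row["hr_q97.5"], np.exp(hi))

    def test_missing_draws_rejected(self, small_cohort):
        res = self._result_with_draws(small_cohort, {"beta1:intercept": np.zeros((1, 10))})
        with pytest.raises(ValueError):
            hazard_ratio_table(res)


def test_percent_change_transformation():
    assert np.isclose(percent_change(0.021), 100 * (np.exp(0.021) - 1))
    assert round(percent_change(0.021), 1) == 2.1


def test_separate_vs_joint_consistency(medium_cohort):
    """With loadings near zero in truth, joint and separate fixed-effect
    estimates agree (the two analysis routes give a consistent result)."""
    from dataclasses import replace

    p = replace(medium_cohort.params, tau=(0.0, 0.0), tau_b=0.0, sigma_nu2=1e-12)
    c = cj.simulate_cohort(250, params=p, seed=77)
    settings = McmcSettings(chains=1, iterations=1200, burn=600, thin=1, seed=8,
                            adapt_interval=25)
    spec = JointModelSpec(longitudinal_terms=LT, survival_terms=ST)
    joint_fit = run_mcmc(c.longitudinal, c.survival, c.covariates, spec, settings)
    sep = cj.fit_parametric_survival(
        c.survival, c.covariates,
        cj.SurvivalModelSpec(baseline="weibull", fixed_effects=[s for s in ST if s != "intercept"]),
    )
    for term in ("age", "female"):
        jm = joint_fit.summaries.loc[f"beta2:{term}", "mean"]
        js = joint_fit.summaries.loc[f"beta2:{term}", "sd"]
        sm_ = sep.coef.loc[term, "estimate"]
        assert abs(jm - sm_) < 4 * max(js, 0.05)
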