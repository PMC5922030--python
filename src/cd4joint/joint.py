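"""Bayesian shared-parameter joint model and its Metropolis-within-Gibbs sampler.

The longitudinal Poisson-log-normal GLMM and the Weibull proportional-hazards
submodel are linked through the patient-level latent effects::

    W1_i(t) = nu0_i + nu1_i * t                      (longitudinal side)
    W2_i    = tau0*nu0_i + tau1*nu1_i + tau_b*log(b_i) + frailty_i

with W2 entering the log hazard (multiplicative frailty).  Inference is
component-wise adaptive random-walk Metropolis within Gibbs: visit-level
perturbations, patient-level effects, fixed effects and loadings move by
random-walk proposals (vectorised across independent patients/observations),
while the variance components use conjugate inverse-gamma / inverse-Wishart
Gibbs draws.  Adaptation of proposal scales is frozen after burn-in.

Model comparison uses the conditional Deviance Information Criterion: the
deviance is the data log-likelihood given the patient-level effects (the
visit-level perturbation is integrated out by quadrature), latents are
plugged in at their posterior means for D_hat, and pD = Dbar - D_hat.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import build_design, coded_time, default_schedule
from .likelihoods import (
    mvn2_loglik,
    normal_loglik,
    pln_marginal_loglik,
    weibull_loglik,
)
from .params import TrueParameters

__all__ = [
    "JointModelSpec",
    "McmcSettings",
    "ModelData",
    "PosteriorResult",
    "DicResult",
    "prepare_data",
    "joint_log_likelihood",
    "run_mcmc",
    "compute_dic",
    "run_ladder",
    "hazard_ratio_table",
    "percent_change",
    "gibbs_variance",
    "LADDER_LEVELS",
]

log = logging.getLogger(__name__)

LADDER_LEVELS = ("fixed_only", "random_intercept", "intercept_slope_frailty")

_ETA_CAP = 30.0


def _exp(eta: np.ndarray) -> np.ndarray:
    return np.exp(np.clip(eta, -_ETA_CAP, _ETA_CAP))


# --------------------------------------------------------------------------
# specification / settings / data containers


@dataclass
class JointModelSpec:
    """Which rung of the random-effects ladder and which variance family.

    ``ladder_level``:

    - ``fixed_only``: no patient random effects, no link (W1 = W2 = 0);
    - ``random_intercept``: random intercept in the longitudinal submodel
      only (W1 = nu0, W2 = 0);
    - ``intercept_slope_frailty``: random intercept and slope, frailty, and
      the shared loadings tau (the full model).

    ``heterogeneous_variance`` switches the visit-level perturbation from a
    common sigma_eps^2 to the patient-specific b_i with log b_i ~ N(0,
    sigma_b^2); the dispersion loading tau_b is active only then (and only
    at the top rung).
    """

    longitudinal_terms: list[str] = field(default_factory=lambda: ["intercept", "time"])
    survival_terms: list[str] = field(default_factory=lambda: ["intercept"])
    ladder_level: str = "intercept_slope_frailty"
    heterogeneous_variance: bool = True
    include_longitudinal: bool = True
    include_survival: bool = True

    def __post_init__(self):
        if self.ladder_level not in LADDER_LEVELS:
            raise ValueError(f"ladder_level must be one of {LADDER_LEVELS}")
        if not (self.include_longitudinal or self.include_survival):
            raise ValueError("at least one submodel must be included")

    # latent-activity flags
    @property
    def nu0_active(self) -> bool:
        return self.include_longitudinal and self.ladder_level != "fixed_only"

    @property
    def nu1_active(self) -> bool:
        return self.include_longitudinal and self.ladder_level == "intercept_slope_frailty"

    @property
    def frailty_active(self) -> bool:
        return self.include_survival and self.ladder_level == "intercept_slope_frailty"

    @property
    def link_active(self) -> bool:
        return (
            self.include_longitudinal
            and self.include_survival
            and self.ladder_level == "intercept_slope_frailty"
        )

    @property
    def logb_active(self) -> bool:
        return self.include_longitudinal and self.heterogeneous_variance

    @property
    def tau_b_active(self) -> bool:
        return self.link_active and self.heterogeneous_variance


@dataclass
class McmcSettings:
    """Sampler settings.  Defaults suit a full analysis; tests scale down."""

    chains: int = 2
    iterations: int = 10_000
    burn: int = 5_000
    thin: int = 2
    seed: int | None = None
    adapt_interval: int = 50
    target_accept: float = 0.3
    prior_beta_sd: float = 10.0
    prior_tau_sd: float = 2.5  # association loadings are soft-identified
    prior_gamma_shape: float = 1.0  # Gamma(1, 1) on rho and phi
    prior_gamma_rate: float = 1.0
    ig_a: float = 2.0  # inverse-gamma prior on variance components
    ig_b: float = 0.2  # prior mean 0.2 on log-scale heterogeneity variances
    iw_df: float = 4.0
    iw_scale: tuple[float, float] = (0.1, 0.01)
    gh_nodes: int = 15
    dic_draws: int = 150
    ess_min: float = 200.0
    geweke_z_max: float = 2.0
    on_nonconvergence: str = "warn"  # "warn" | "error"

    def __post_init__(self):
        if self.burn >= self.iterations:
            raise ValueError("burn must be smaller than iterations")
        if self.on_nonconvergence not in ("warn", "error"):
            raise ValueError("on_nonconvergence must be 'warn' or 'error'")


@dataclass
class ModelData:
    """Aligned numeric arrays for one cohort (see :func:`prepare_data`)."""

    # longitudinal (rows with an observed change)
    y: np.ndarray | None
    pat: np.ndarray | None
    X1: np.ndarray | None
    tstd: np.ndarray | None
    long_terms: list[str]
    # survival (one row per patient, covariate order)
    t: np.ndarray | None
    delta: np.ndarray | None
    X2: np.ndarray | None
    surv_terms: list[str]
    n: int
    patient_ids: np.ndarray
    X1p: np.ndarray | None = None  # patient-level longitudinal design (time col = 0)

    @property
    def m(self) -> int:
        return 0 if self.y is None else len(self.y)


def prepare_data(
    longitudinal: pd.DataFrame | None,
    survival: pd.DataFrame | None,
    covariates: pd.DataFrame,
    long_terms: list[str],
    surv_terms: list[str],
    schedule: np.ndarray | None = None,
) -> ModelData:
    """Assemble fitting arrays from the three-table schema.

    Longitudinal rows enter when observed with a defined change (visit 2
    onward); the time covariate is the visit index with its origin at the
    first modelled change visit (see :func:`cd4joint.design.coded_time`).
    Survival rows are aligned to the covariate table's patient order.
    """
    ids = covariates["patient_id"].to_numpy()
    index = pd.Series(np.arange(len(ids)), index=ids)
    n = len(ids)

    y = pat = X1 = tstd = X1p = None
    if longitudinal is not None:
        obs = longitudinal[
            longitudinal.get("observed", True) & longitudinal["cd4_change"].notna()
        ]
        missing = set(obs["patient_id"]) - set(ids)
        if missing:
            raise ValueError(f"longitudinal table has patients not in covariates: {sorted(missing)[:5]}")
        pat = index[obs["patient_id"]].to_numpy()
        y = obs["cd4_change"].to_numpy(dtype=float)
        if schedule is None:
            schedule = default_schedule()
        tstd = coded_time(obs["visit_index"].to_numpy(dtype=float), len(schedule))
        X1 = build_design(covariates, long_terms, time_std=tstd, row_patient=pat)
        X1p = build_design(
            covariates, long_terms, time_std=np.zeros(n), row_patient=np.arange(n)
        )

    t = delta = X2 = None
    if survival is not None:
        surv = survival.set_index("patient_id").loc[ids]
        t = surv["time"].to_numpy(dtype=float)
        delta = surv["event"].to_numpy(dtype=float)
        if np.any(t <= 0):
            raise ValueError("survival times must be positive")
        X2 = build_design(covariates, [s for s in surv_terms if s != "time"])

    return ModelData(
        y=y, pat=pat, X1=X1, tstd=tstd, long_terms=list(long_terms),
        t=t, delta=delta, X2=X2, surv_terms=[s for s in surv_terms if s != "time"],
        n=n, patient_ids=ids, X1p=X1p,
    )


# --------------------------------------------------------------------------
# joint likelihood (used directly and as the DIC deviance kernel)


def joint_log_likelihood(
    params: TrueParameters,
    latents: pd.DataFrame,
    data: ModelData,
    nodes: int = 25,
    return_parts: bool = False,
):
    """Joint log-likelihood at given parameters and patient-level latents.

    Sum over patients of (a) the Poisson-log-normal longitudinal log density
    given (nu_i, b_i) — the visit perturbation integrated out by quadrature,
    (b) the censored Weibull log density with log hazard x'beta2 + W2_i, and
    (c) the latent-effect log priors.
    """
    nu0 = latents["nu0"].to_numpy(dtype=float)
    nu1 = latents["nu1"].to_numpy(dtype=float)
    logb = latents["log_b"].to_numpy(dtype=float)
    frail = latents["frailty"].to_numpy(dtype=float)
    if len(nu0) != data.n:
        raise ValueError("one latent row per patient required")

    parts = {"longitudinal": 0.0, "survival": 0.0, "latent_priors": 0.0}
    if data.y is not None:
        beta1 = np.array([params.beta1[t] for t in data.long_terms])
        eta1 = data.X1 @ beta1 + nu0[data.pat] + nu1[data.pat] * data.tstd
        parts["longitudinal"] = pln_marginal_loglik(
            data.y, eta1, np.exp(logb)[data.pat], nodes=nodes
        )
    if data.t is not None:
        beta2 = np.array([params.beta2[t] for t in data.surv_terms])
        tau0, tau1 = params.tau
        w2 = tau0 * nu0 + tau1 * nu1 + params.tau_b * logb + frail
        eta2 = (data.X2 @ beta2 if data.surv_terms else 0.0) + w2
        parts["survival"] = weibull_loglik(data.t, data.delta, eta2, params.rho, params.phi)
    parts["latent_priors"] = (
        mvn2_loglik(nu0, nu1, params.Sigma_nu)
        + normal_loglik(logb, params.sigma_b2)
        + normal_loglik(frail, params.sigma_nu2)
    )
    total = sum(parts.values())
    if not np.isfinite(total):
        bad = [k for k, v in parts.items() if not np.isfinite(v)]
        raise FloatingPointError(f"non-finite joint log-likelihood in terms: {bad}")
    return (total, parts) if return_parts else total


def gibbs_variance(rng: np.random.Generator, x: np.ndarray, a0: float, b0: float) -> float:
    """Conjugate inverse-gamma draw for a variance given zero-mean normals.

    Posterior is IG(a0 + n/2, b0 + sum(x^2)/2).
    """
    x = np.asarray(x, dtype=float)
    a = a0 + 0.5 * len(x)
    b = b0 + 0.5 * float(np.sum(x**2))
    return b / rng.gamma(a)


# --------------------------------------------------------------------------
# the sampler


class _Stepper:
    """Adaptive random-walk scales, frozen after burn-in."""

    def __init__(self, scales: dict[str, float], target, interval):
        self.scale = dict(scales)
        self.acc = {k: 0.0 for k in self.scale}
        self.tries = {k: 0.0 for k in self.scale}
        self.target = target
        self.interval = interval
        self.frozen = False

    def record(self, name, rate, weight=1.0):
        self.acc[name] += rate * weight
        self.tries[name] += weight

    def adapt(self):
        if self.frozen:
            return
        for k in self.scale:
            if self.tries[k] > 0:
                rate = self.acc[k] / self.tries[k]
                self.scale[k] = float(
                    np.clip(self.scale[k] * np.exp(0.9 * (rate - self.target)), 1e-5, 20.0)
                )
                self.acc[k] = 0.0
                self.tries[k] = 0.0

    def rates(self):
        return {
            k: (self.acc[k] / self.tries[k] if self.tries[k] else np.nan)
            for k in self.scale
        }


class _Chain:
    def __init__(self, data: ModelData, spec: JointModelSpec, st: McmcSettings, rng):
        self.d, self.spec, self.st, self.rng = data, spec, st, rng
        n, m = data.n, data.m
        self.beta1 = np.zeros(len(data.long_terms)) if data.y is not None else np.zeros(0)
        self.beta2 = np.zeros(len(data.surv_terms)) if data.t is not None else np.zeros(0)
        self.nu0 = np.zeros(n)
        self.nu1 = np.zeros(n)
        self.logb = np.zeros(n)
        self.frail = np.zeros(n)
        self.eps = np.zeros(m)
        self.tau0 = 0.0
        self.tau1 = 0.0
        self.tau_b = 0.0
        self.log_rho = 0.0
        self.log_phi = 0.0
        self.Sigma = np.array([[0.3, 0.0], [0.0, 0.05]])
        self.sigma_b2 = 0.2
        self.sigma_nu2 = 0.2
        self.sigma_e2 = 0.3
        if data.y is not None:
            self.cnt = np.bincount(data.pat, minlength=n).astype(float)
            # relative proposal scales ~ 1/sqrt(information): high-count rows
            # and high-count patients need proportionally finer moves
            sy = np.bincount(data.pat, weights=data.y, minlength=n)
            syt2 = np.bincount(data.pat, weights=data.y * data.tstd**2, minlength=n)
            tsum = np.bincount(data.pat, weights=data.tstd, minlength=n)
            tbar = tsum / np.maximum(self.cnt, 1.0)
            sydev = np.bincount(
                data.pat, weights=data.y * (data.tstd - tbar[data.pat]) ** 2, minlength=n
            )
            self._r_eps = 1.0 / np.sqrt(1.0 + data.y)
            self._r_nu0 = 1.0 / np.sqrt(1.0 + sy)
            self._r_nu1 = 1.0 / np.sqrt(1.0 + syt2)
            self._r_ridge = 1.0 / np.sqrt(1.0 + sydev)
            self._r_logb = 1.0 / np.sqrt(1.0 + self.cnt)
            self._tbar = tbar
        else:
            self._r_nu0 = self._r_nu1 = self._r_ridge = self._r_logb = np.ones(n)
            self._tbar = np.zeros(n)
        scales = {"eps": 2.0, "nu0": 2.0, "nu1": 2.0, "logb": 1.0, "frail": 0.5,
                  "log_rho": 0.1, "log_phi": 0.1, "tau0": 0.3, "tau1": 0.5,
                  "tau_b": 0.5, "frail_scale": 0.2, "nu_ridge": 2.0}
        scales.update({f"b1_{i}": 0.05 for i in range(len(self.beta1))})
        scales.update({f"b2_{i}": 0.1 for i in range(len(self.beta2))})
        self.steps = _Stepper(scales, st.target_accept, st.adapt_interval)
        self._init_from_mle()

    # -- initialisation from quick classical fits (jittered per chain)
    #
    # The marginal (no-random-effects) GLM slope of time is inflated by
    # survivor composition when steep-slope patients stay longest, and a
    # sampler started there can settle in a self-consistent wrong basin
    # where the fixed time effect absorbs the selection.  The time effect
    # and the random slopes are therefore initialised from *within-patient*
    # regressions, and the association loadings from a Weibull fit on the
    # initial latent estimates.
    def _init_from_mle(self):
        d, rng, spec = self.d, self.rng, self.spec
        if d.y is not None:
            try:
                import statsmodels.api as sm

                res = sm.GLM(d.y, d.X1, family=sm.families.Poisson()).fit()
                self.beta1 = np.asarray(res.params, dtype=float)
                for i, se in enumerate(np.asarray(res.bse, dtype=float)):
                    if np.isfinite(se) and se > 0:
                        self.steps.scale[f"b1_{i}"] = float(np.clip(2.4 * se, 1e-4, 0.5))
            except Exception:  # pragma: no cover - fallback path
                if "intercept" in d.long_terms:
                    self.beta1[d.long_terms.index("intercept")] = np.log(max(d.y.mean(), 0.1))
            self.beta1 = self.beta1 + 0.01 * rng.standard_normal(len(self.beta1))
            t_idx = d.long_terms.index("time") if "time" in d.long_terms else None
            if t_idx is not None and spec.nu0_active:
                # within-patient log-count slopes
                ly = np.log(d.y + 0.5)
                t = d.tstd
                cnt = self.cnt
                st_ = np.bincount(d.pat, weights=t, minlength=d.n)
                sy = np.bincount(d.pat, weights=ly, minlength=d.n)
                stt = np.bincount(d.pat, weights=t * t, minlength=d.n)
                sty = np.bincount(d.pat, weights=t * ly, minlength=d.n)
                with np.errstate(all="ignore"):
                    sxx = stt - st_**2 / np.maximum(cnt, 1.0)
                    sxy = sty - st_ * sy / np.maximum(cnt, 1.0)
                    slope = np.where(sxx > 1e-9, sxy / np.maximum(sxx, 1e-9), np.nan)
                good = np.isfinite(slope) & (cnt >= 3)
                if good.any():
                    bt = float(np.median(slope[good]))
                    self.beta1[t_idx] = bt
                    if spec.nu1_active:
                        shrink = sxx / (sxx + 50.0)  # unit-ish noise vs weak prior
                        self.nu1 = np.where(good, np.clip((slope - bt) * shrink, -1, 1), 0.0)
            if spec.nu0_active:
                # random intercepts from per-patient residual ratios
                mu = _exp(d.X1 @ self.beta1 + self.nu1[d.pat] * d.tstd)
                sy = np.bincount(d.pat, weights=d.y, minlength=d.n)
                smu = np.bincount(d.pat, weights=mu, minlength=d.n)
                self.nu0 = np.clip(np.log((sy + 0.5) / (smu + 0.5)), -3.0, 3.0)
                self.Sigma[0, 0] = max(float(self.nu0.var()), 0.05)
                if spec.nu1_active:
                    self.Sigma[1, 1] = max(float(self.nu1.var()), 0.002)
            # visit perturbations from per-row residual ratios
            mu_row = _exp(d.X1 @ self.beta1 + self.nu0[d.pat] + self.nu1[d.pat] * d.tstd)
            self.eps = np.clip(np.log((d.y + 0.5) / (mu_row + 0.5)), -3.0, 3.0)
        if d.t is not None:
            try:
                from .survival import _weibull_ml

                X2 = d.X2 if len(d.surv_terms) else np.empty((d.n, 0))
                aug = [X2]
                if spec.link_active:
                    aug += [self.nu0[:, None], self.nu1[:, None]]
                Xa = np.hstack(aug)
                fit = _weibull_ml(d.t, d.delta, Xa if Xa.shape[1] else None)
                self.log_phi, self.log_rho = fit[0], fit[1]
                coefs = np.asarray(fit[2:], dtype=float)
                if len(d.surv_terms):
                    self.beta2 = coefs[: len(d.surv_terms)]
                    if "intercept" in d.surv_terms:
                        # phi and an intercept are aliased; keep phi = 1
                        self.beta2[d.surv_terms.index("intercept")] += self.log_phi
                        self.log_phi = 0.0
                if spec.link_active:
                    self.tau0 = float(np.clip(coefs[len(d.surv_terms)], -4, 4))
                    self.tau1 = float(np.clip(coefs[len(d.surv_terms) + 1], -4, 4))
            except Exception:  # pragma: no cover - fallback path
                pass
            self.beta2 = self.beta2 + 0.01 * rng.standard_normal(len(self.beta2))
            self.log_rho += 0.01 * rng.standard_normal()

    # -- cached linear predictors
    def eta1(self):
        d = self.d
        return d.X1 @ self.beta1 + self.nu0[d.pat] + self.nu1[d.pat] * d.tstd + self.eps

    def w2(self):
        return self.tau0 * self.nu0 + self.tau1 * self.nu1 + self.tau_b * self.logb + self.frail

    def eta2(self):
        d = self.d
        base = d.X2 @ self.beta2 if len(self.beta2) else np.zeros(d.n)
        return base + self.w2()

    # -- one full Metropolis-within-Gibbs sweep
    def sweep(self, frailty_released: bool = True):
        # the frailty block is kept frozen early in burn-in so the fixed
        # effects and shape settle first; otherwise early misfit is absorbed
        # into the frailty spread and the chain climbs the variance funnel
        self._frailty_on = frailty_released
        d, spec, st, rng = self.d, self.spec, self.st, self.rng
        if d.y is not None:
            self._update_eps()
        if spec.nu0_active or spec.nu1_active or spec.logb_active or spec.frailty_active:
            self._update_latents()
        if d.y is not None:
            self._update_beta1()
        if d.t is not None:
            self._update_survival_params()
        if spec.nu0_active:
            self._recenter_longitudinal()
        if spec.frailty_active and self._frailty_on:
            self._recenter_survival()
        self._update_variances()
        if spec.frailty_active and self._frailty_on:
            self._rescale_frailty()

    def _var_eps(self):
        d = self.d
        if self.spec.logb_active:
            return np.exp(self.logb)[d.pat]
        return np.full(d.m, self.sigma_e2)

    def _update_eps(self):
        d, rng = self.d, self.rng
        s = self.steps.scale["eps"]
        eta = self.eta1()
        prop = self.eps + s * self._r_eps * rng.standard_normal(d.m)
        deta = prop - self.eps
        var = self._var_eps()
        logacc = (
            d.y * deta
            - (_exp(eta + deta) - _exp(eta))
            - 0.5 * (prop**2 - self.eps**2) / var
        )
        acc = np.log(rng.uniform(size=d.m)) < logacc
        self.eps = np.where(acc, prop, self.eps)
        self.steps.record("eps", float(acc.mean()))

    def _surv_cache(self):
        d = self.d
        eta2 = self.eta2()
        Hb = np.exp(self.log_phi) * d.t ** np.exp(self.log_rho)
        return eta2, Hb

    def _update_latents(self):
        d, spec, rng = self.d, self.spec, self.rng
        n = d.n
        have_long = d.y is not None
        have_surv = d.t is not None
        eta = self.eta1() if have_long else None
        mu = _exp(eta) if have_long else None
        if have_surv:
            eta2, Hb = self._surv_cache()
            ch = Hb * _exp(eta2)  # cumulative hazard per patient

        # precision of (nu0, nu1) prior
        if spec.nu1_active:
            det = self.Sigma[0, 0] * self.Sigma[1, 1] - self.Sigma[0, 1] ** 2
            P00 = self.Sigma[1, 1] / det
            P11 = self.Sigma[0, 0] / det
            P01 = -self.Sigma[0, 1] / det
        else:
            P00 = 1.0 / self.Sigma[0, 0]
            P11 = P01 = 0.0

        def long_delta(deta_rows):
            dll = d.y * deta_rows - (_exp(eta + deta_rows) - mu)
            return np.bincount(d.pat, weights=dll, minlength=n)

        if spec.nu0_active:
            s = self.steps.scale["nu0"]
            dlt = s * self._r_nu0 * rng.standard_normal(n)
            logacc = long_delta(dlt[d.pat])
            logacc -= 0.5 * P00 * ((self.nu0 + dlt) ** 2 - self.nu0**2) + P01 * self.nu1 * dlt
            if spec.link_active:
                de2 = self.tau0 * dlt
                logacc += d.delta * de2 - ch * (np.exp(de2) - 1.0)
            acc = np.log(rng.uniform(size=n)) < logacc
            self.nu0 = self.nu0 + np.where(acc, dlt, 0.0)
            if have_long:
                eta = eta + np.where(acc, dlt, 0.0)[d.pat]
                mu = _exp(eta)
            if spec.link_active:
                upd = self.tau0 * np.where(acc, dlt, 0.0)
                eta2 = eta2 + upd
                ch = ch * np.exp(upd)
            self.steps.record("nu0", float(acc.mean()))

        if spec.nu1_active:
            s = self.steps.scale["nu1"]
            dlt = s * self._r_nu1 * rng.standard_normal(n)
            logacc = long_delta(dlt[d.pat] * d.tstd)
            logacc -= 0.5 * P11 * ((self.nu1 + dlt) ** 2 - self.nu1**2) + P01 * self.nu0 * dlt
            if spec.link_active:
                de2 = self.tau1 * dlt
                logacc += d.delta * de2 - ch * (np.exp(de2) - 1.0)
            acc = np.log(rng.uniform(size=n)) < logacc
            self.nu1 = self.nu1 + np.where(acc, dlt, 0.0)
            if have_long:
                eta = eta + (np.where(acc, dlt, 0.0)[d.pat]) * d.tstd
                mu = _exp(eta)
            if spec.link_active:
                upd = self.tau1 * np.where(acc, dlt, 0.0)
                eta2 = eta2 + upd
                ch = ch * np.exp(upd)
            self.steps.record("nu1", float(acc.mean()))

        if spec.nu1_active:
            # ridge move: change a patient's slope while holding the level
            # at that patient's mean observed time fixed — the direction the
            # separate nu0/nu1 random walks mix worst along
            tbar = self._tbar
            s = self.steps.scale["nu_ridge"]
            dlt = s * self._r_ridge * rng.standard_normal(n)
            new0 = self.nu0 - dlt * tbar
            new1 = self.nu1 + dlt
            logacc = long_delta(dlt[d.pat] * (d.tstd - tbar[d.pat])) if have_long else np.zeros(n)
            quad_old = (P00 * self.nu0**2 + 2 * P01 * self.nu0 * self.nu1 + P11 * self.nu1**2)
            quad_new = P00 * new0**2 + 2 * P01 * new0 * new1 + P11 * new1**2
            logacc -= 0.5 * (quad_new - quad_old)
            if spec.link_active:
                de2 = self.tau1 * dlt - self.tau0 * dlt * tbar
                logacc += d.delta * de2 - ch * (np.exp(de2) - 1.0)
            acc = np.log(rng.uniform(size=n)) < logacc
            self.nu0 = np.where(acc, new0, self.nu0)
            self.nu1 = np.where(acc, new1, self.nu1)
            if have_long:
                upd = np.where(acc, dlt, 0.0)
                eta = eta + upd[d.pat] * (d.tstd - tbar[d.pat])
                mu = _exp(eta)
            if spec.link_active:
                upd2 = np.where(acc, self.tau1 * dlt - self.tau0 * dlt * tbar, 0.0)
                eta2 = eta2 + upd2
                ch = ch * np.exp(upd2)
            self.steps.record("nu_ridge", float(acc.mean()))

        if spec.logb_active:
            s = self.steps.scale["logb"]
            dlt = s * self._r_logb * rng.standard_normal(n)
            Se = np.bincount(d.pat, weights=self.eps**2, minlength=n)
            b_old = np.exp(self.logb)
            b_new = np.exp(self.logb + dlt)
            logacc = (
                -0.5 * self.cnt * dlt
                - 0.5 * Se * (1.0 / b_new - 1.0 / b_old)
                - 0.5 * ((self.logb + dlt) ** 2 - self.logb**2) / self.sigma_b2
            )
            if spec.tau_b_active:
                de2 = self.tau_b * dlt
                logacc += d.delta * de2 - ch * (np.exp(de2) - 1.0)
            acc = np.log(rng.uniform(size=n)) < logacc
            upd = np.where(acc, dlt, 0.0)
            self.logb = self.logb + upd
            if spec.tau_b_active:
                eta2 = eta2 + self.tau_b * upd
                ch = ch * np.exp(self.tau_b * upd)
            self.steps.record("logb", float(acc.mean()))

        if spec.frailty_active and self._frailty_on:
            s = self.steps.scale["frail"]
            dlt = s * rng.standard_normal(n)
            logacc = (
                d.delta * dlt
                - ch * (np.exp(dlt) - 1.0)
                - 0.5 * ((self.frail + dlt) ** 2 - self.frail**2) / self.sigma_nu2
            )
            acc = np.log(rng.uniform(size=n)) < logacc
            self.frail = self.frail + np.where(acc, dlt, 0.0)
            self.steps.record("frail", float(acc.mean()))

    def _update_beta1(self):
        d, rng, st = self.d, self.rng, self.st
        eta = self.eta1()
        mu = _exp(eta)
        for k in range(len(self.beta1)):
            s = self.steps.scale[f"b1_{k}"]
            dlt = s * rng.standard_normal()
            deta = dlt * d.X1[:, k]
            logacc = float(np.sum(d.y * deta - (_exp(eta + deta) - mu)))
            logacc -= ((self.beta1[k] + dlt) ** 2 - self.beta1[k] ** 2) / (
                2 * st.prior_beta_sd**2
            )
            if np.log(rng.uniform()) < logacc:
                self.beta1[k] += dlt
                eta = eta + deta
                mu = _exp(eta)
                self.steps.record(f"b1_{k}", 1.0)
            else:
                self.steps.record(f"b1_{k}", 0.0)

    def _surv_loglik(self, eta2, log_rho, log_phi):
        d = self.d
        rho, phi = np.exp(log_rho), np.exp(log_phi)
        logh = log_phi + log_rho + (rho - 1.0) * self._logt + np.clip(eta2, -_ETA_CAP, _ETA_CAP)
        H = phi * d.t**rho * _exp(eta2)
        return float(np.sum(d.delta * logh - H))

    def _update_survival_params(self):
        d, rng, st, spec = self.d, self.rng, self.st, self.spec
        if not hasattr(self, "_logt"):
            self._logt = np.log(d.t)
        base = d.X2 @ self.beta2 if len(self.beta2) else np.zeros(d.n)
        w2 = self.w2()
        cur = self._surv_loglik(base + w2, self.log_rho, self.log_phi)

        for k in range(len(self.beta2)):
            s = self.steps.scale[f"b2_{k}"]
            dlt = s * rng.standard_normal()
            new = self._surv_loglik(base + dlt * d.X2[:, k] + w2, self.log_rho, self.log_phi)
            logacc = new - cur - ((self.beta2[k] + dlt) ** 2 - self.beta2[k] ** 2) / (
                2 * st.prior_beta_sd**2
            )
            if np.log(rng.uniform()) < logacc:
                self.beta2[k] += dlt
                base = base + dlt * d.X2[:, k]
                cur = new
                self.steps.record(f"b2_{k}", 1.0)
            else:
                self.steps.record(f"b2_{k}", 0.0)

        loadings = []
        if spec.link_active:
            loadings += [("tau0", self.nu0), ("tau1", self.nu1)]
        if spec.tau_b_active:
            loadings.append(("tau_b", self.logb))
        for name, vec in loadings:
            s = self.steps.scale[name]
            dlt = s * rng.standard_normal()
            val = getattr(self, name)
            new = self._surv_loglik(base + w2 + dlt * vec, self.log_rho, self.log_phi)
            logacc = new - cur - ((val + dlt) ** 2 - val**2) / (2 * st.prior_tau_sd**2)
            if np.log(rng.uniform()) < logacc:
                setattr(self, name, val + dlt)
                w2 = w2 + dlt * vec
                cur = new
                self.steps.record(name, 1.0)
            else:
                self.steps.record(name, 0.0)

        # rho and phi: log-scale random walk with Gamma(a, r) priors
        a, r = st.prior_gamma_shape, st.prior_gamma_rate
        for name in ("log_rho", "log_phi"):
            if name == "log_phi" and "intercept" in d.surv_terms:
                continue  # aliased with the survival intercept; keep phi = 1
            s = self.steps.scale[name]
            dlt = s * rng.standard_normal()
            val = getattr(self, name)
            lr = self.log_rho + (dlt if name == "log_rho" else 0.0)
            lp = self.log_phi + (dlt if name == "log_phi" else 0.0)
            new = self._surv_loglik(base + w2, lr, lp)
            # Gamma(a, r) prior on the natural scale plus log-scale Jacobian
            logacc = (
                new
                - cur
                + a * ((val + dlt) - val)
                - r * (np.exp(val + dlt) - np.exp(val))
            )
            if np.log(rng.uniform()) < logacc:
                setattr(self, name, val + dlt)
                cur = new
                self.steps.record(name, 1.0)
            else:
                self.steps.record(name, 0.0)

    # -- recentering (metropolized Gibbs along likelihood-invariant directions)
    #
    # A fixed effect and the latent effect it is aliased with (patient-level
    # covariate <-> nu0, standardized time <-> nu1, survival covariate or
    # loading <-> frailty) are moved jointly along the direction that leaves
    # the data likelihood unchanged.  The Gaussian priors make the exact
    # conditional of the shift available; proposing from it cancels every
    # Gaussian term, so the acceptance ratio reduces to the survival-link
    # ratio (and to 1 where the direction leaves the hazard invariant too).

    def _recenter_longitudinal(self):
        d, spec, st, rng = self.d, self.spec, self.st, self.rng
        sb2 = st.prior_beta_sd**2
        if spec.nu1_active:
            det = self.Sigma[0, 0] * self.Sigma[1, 1] - self.Sigma[0, 1] ** 2
            P00, P11, P01 = self.Sigma[1, 1] / det, self.Sigma[0, 0] / det, -self.Sigma[0, 1] / det
        else:
            P00, P11, P01 = 1.0 / self.Sigma[0, 0], 0.0, 0.0
        link = spec.link_active
        if link:
            eta2, Hb = self._surv_cache()
            ch = Hb * _exp(eta2)
        for k, term in enumerate(d.long_terms):
            if term == "time":
                if not spec.nu1_active:
                    continue
                prec = P11 * d.n + 1.0 / sb2
                lin = P11 * self.nu1.sum() + P01 * self.nu0.sum() - self.beta1[k] / sb2
                tau, x = self.tau1, None
            else:
                x = d.X1p[:, k]
                prec = P00 * float(x @ x) + 1.0 / sb2
                lin = P00 * float(x @ self.nu0) + P01 * float(x @ self.nu1) - self.beta1[k] / sb2
                tau = self.tau0
            dlt = rng.normal(lin / prec, 1.0 / np.sqrt(prec))
            if link and tau != 0.0:
                de2 = -tau * dlt * (x if x is not None else 1.0)
                logacc = float(np.sum(d.delta * de2 - ch * (np.exp(de2) - 1.0)))
                if np.log(rng.uniform()) >= logacc:
                    continue
                eta2 = eta2 + de2
                ch = ch * np.exp(de2)
            self.beta1[k] += dlt
            if term == "time":
                self.nu1 = self.nu1 - dlt
            else:
                self.nu0 = self.nu0 - dlt * x

    def _recenter_survival(self):
        d, spec, st, rng = self.d, self.spec, self.st, self.rng
        sb2 = st.prior_beta_sd**2
        directions = [(f"b2_{k}", d.X2[:, k]) for k in range(len(self.beta2))]
        if spec.link_active:
            directions += [("tau0", self.nu0), ("tau1", self.nu1)]
        if spec.tau_b_active:
            directions.append(("tau_b", self.logb))
        for name, x in directions:
            xx = float(x @ x)
            psd2 = sb2 if name.startswith("b2_") else st.prior_tau_sd**2
            prec = xx / self.sigma_nu2 + 1.0 / psd2
            if name.startswith("b2_"):
                k = int(name[3:])
                val = self.beta2[k]
            else:
                val = getattr(self, name)
            lin = float(x @ self.frail) / self.sigma_nu2 - val / psd2
            dlt = rng.normal(lin / prec, 1.0 / np.sqrt(prec))
            # W2 is invariant along this direction: exact Gibbs, always accept
            if name.startswith("b2_"):
                self.beta2[k] += dlt
            else:
                setattr(self, name, val + dlt)
            self.frail = self.frail - dlt * x

    def _update_variances(self):
        d, spec, st, rng = self.d, self.spec, self.st, self.rng
        if spec.nu1_active:
            M = np.array(
                [
                    [np.sum(self.nu0**2), np.sum(self.nu0 * self.nu1)],
                    [np.sum(self.nu0 * self.nu1), np.sum(self.nu1**2)],
                ]
            )
            S0 = np.diag(st.iw_scale)
            self.Sigma = stats.invwishart.rvs(
                df=st.iw_df + d.n, scale=S0 + M, random_state=rng
            )
        elif spec.nu0_active:
            self.Sigma[0, 0] = gibbs_variance(rng, self.nu0, st.ig_a, st.ig_b)
        if spec.logb_active:
            self.sigma_b2 = gibbs_variance(rng, self.logb, st.ig_a, st.ig_b)
        elif d.y is not None:
            self.sigma_e2 = gibbs_variance(rng, self.eps, st.ig_a, st.ig_b)
        if spec.frailty_active and self._frailty_on:
            self.sigma_nu2 = gibbs_variance(rng, self.frail, st.ig_a, st.ig_b)

    def _rescale_frailty(self):
        # interweaving move: rescale the frailty vector and its variance
        # together, (frail, s2) -> (c*frail, c^2*s2).  The non-centered
        # residuals are held fixed, so the normal latent prior contributes
        # only through the Jacobian; this breaks the funnel coupling between
        # the frailty spread and its variance component.
        d, st, rng = self.d, self.st, self.rng
        s = self.steps.scale["frail_scale"]
        dlt = s * rng.standard_normal()
        c = np.exp(dlt)
        eta2, Hb = self._surv_cache()
        ch = Hb * _exp(eta2)
        de2 = self.frail * (c - 1.0)
        logacc = float(np.sum(d.delta * de2 - ch * (np.exp(de2) - 1.0)))
        # prior on s2 (inverse gamma), latent density change + Jacobian
        logacc += 2.0 * dlt - 2.0 * (st.ig_a + 1.0) * dlt
        logacc -= st.ig_b / self.sigma_nu2 * (np.exp(-2.0 * dlt) - 1.0)
        if np.log(rng.uniform()) < logacc:
            self.frail = self.frail * c
            self.sigma_nu2 = self.sigma_nu2 * c * c
            self.steps.record("frail_scale", 1.0)
        else:
            self.steps.record("frail_scale", 0.0)

    # -- scalar snapshot for storage
    def scalars(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for i, t in enumerate(self.d.long_terms):
            if self.d.y is not None:
                out[f"beta1:{t}"] = self.beta1[i]
        for i, t in enumerate(self.d.surv_terms):
            if self.d.t is not None:
                out[f"beta2:{t}"] = self.beta2[i]
        if self.d.t is not None:
            out["rho"] = np.exp(self.log_rho)
            if "intercept" not in self.d.surv_terms:  # else phi fixed at 1
                out["phi"] = np.exp(self.log_phi)
        if self.spec.link_active:
            out["tau0"] = self.tau0
            out["tau1"] = self.tau1
        if self.spec.tau_b_active:
            out["tau_b"] = self.tau_b
        if self.spec.nu0_active:
            out["var_nu0"] = self.Sigma[0, 0]
        if self.spec.nu1_active:
            out["var_nu1"] = self.Sigma[1, 1]
            out["cov_nu01"] = self.Sigma[0, 1]
            out["corr_nu01"] = self.Sigma[0, 1] / np.sqrt(
                self.Sigma[0, 0] * self.Sigma[1, 1]
            )
        if self.spec.logb_active:
            out["sigma_b2"] = self.sigma_b2
        elif self.d.y is not None:
            out["sigma_e2"] = self.sigma_e2
        if self.spec.frailty_active:
            out["sigma_nu2"] = self.sigma_nu2
        return out


# --------------------------------------------------------------------------
# results


@dataclass
class DicResult:
    dbar: float
    dhat: float
    p_d: float
    dic: float

    def as_tuple(self):
        return (self.dbar, self.dhat, self.p_d, self.dic)


@dataclass
class PosteriorResult:
    """Posterior draws, summaries, DIC components and diagnostics."""

    draws: dict[str, np.ndarray]  # name -> (chains, ndraws)
    latent_draws: dict[str, np.ndarray]  # name -> (chains, ndraws, n)
    summaries: pd.DataFrame
    convergence: pd.DataFrame
    accept_rates: dict[str, float]
    spec: JointModelSpec
    settings: McmcSettings
    data: ModelData
    dic: DicResult | None = None

    def stacked(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def latent_mean(self, name: str) -> np.ndarray:
        return self.latent_draws[name].mean(axis=(0, 1))


def _geweke_z(x: np.ndarray) -> float:
    """Max |z| over chains comparing the first 10% to the last 50% of draws."""
    zs = []
    for row in np.atleast_2d(x):
        n = len(row)
        if n < 20:
            return np.nan
        a = row[: max(2, n // 10)]
        b = row[n // 2 :]
        va = a.var(ddof=1) / len(a)
        vb = b.var(ddof=1) / len(b)
        if va + vb == 0:
            zs.append(0.0)
        else:
            zs.append(abs(a.mean() - b.mean()) / np.sqrt(va + vb))
    return float(max(zs))


def _diagnostics(draws: dict[str, np.ndarray], st: McmcSettings) -> pd.DataFrame:
    import arviz as az

    rows = []
    for name, arr in draws.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess = float(az.ess(np.asarray(arr)))
            rhat = float(az.rhat(np.asarray(arr))) if arr.shape[0] > 1 else np.nan
        z = _geweke_z(arr)
        rows.append(
            {
                "parameter": name,
                "geweke_z": z,
                "ess": ess,
                "rhat": rhat,
                "ok": bool((not np.isfinite(z) or z < st.geweke_z_max) and ess >= st.ess_min),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def _summaries(draws: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for name, arr in draws.items():
        flat = arr.reshape(-1)
        lo, hi = np.quantile(flat, [0.025, 0.975])
        rows.append(
            {
                "parameter": name,
                "mean": flat.mean(),
                "sd": flat.std(ddof=1),
                "q2.5": lo,
                "q97.5": hi,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def run_mcmc(
    longitudinal: pd.DataFrame | None,
    survival: pd.DataFrame | None,
    covariates: pd.DataFrame,
    spec: JointModelSpec,
    settings: McmcSettings | None = None,
    schedule: np.ndarray | None = None,
    data: ModelData | None = None,
) -> PosteriorResult:
    """Run the Metropolis-within-Gibbs sampler for the joint model.

    Reproducible under a fixed seed; convergence diagnostics (Geweke z,
    effective sample size, split R-hat) are attached and, depending on
    ``settings.on_nonconvergence``, marginal diagnostics warn or raise.
    """
    st = settings or McmcSettings()
    if data is None:
        data = prepare_data(
            longitudinal if spec.include_longitudinal else None,
            survival if spec.include_survival else None,
            covariates,
            spec.longitudinal_terms,
            spec.survival_terms,
            schedule=schedule,
        )
    ss = np.random.SeedSequence(st.seed)
    chain_seeds = ss.spawn(st.chains)

    all_scalars: list[dict[str, list[float]]] = []
    all_latents: list[dict[str, list[np.ndarray]]] = []
    acc_rates: dict[str, float] = {}
    for c in range(st.chains):
        rng = np.random.default_rng(chain_seeds[c])
        chain = _Chain(data, spec, st, rng)
        scal: dict[str, list[float]] = {}
        lat: dict[str, list[np.ndarray]] = {"nu0": [], "nu1": [], "logb": [], "frail": []}
        acc_accum: dict[str, list[float]] = {}
        release_at = int(0.4 * st.burn)
        for it in range(st.iterations):
            chain.sweep(frailty_released=it >= release_at)
            if it < st.burn:
                if (it + 1) % st.adapt_interval == 0:
                    for k, v in chain.steps.rates().items():
                        acc_accum.setdefault(k, []).append(v)
                    chain.steps.adapt()
                if it == st.burn - 1:
                    chain.steps.frozen = True
            elif (it - st.burn) % st.thin == 0:
                for k, v in chain.scalars().items():
                    scal.setdefault(k, []).append(float(v))
                lat["nu0"].append(chain.nu0.copy())
                lat["nu1"].append(chain.nu1.copy())
                lat["logb"].append(chain.logb.copy())
                lat["frail"].append(chain.frail.copy())
        all_scalars.append(scal)
        all_latents.append(lat)
        if c == 0:
            acc_rates = {
                k: float(np.nanmean(v))
                for k, v in acc_accum.items()
                if len(v) and not np.all(np.isnan(v))
            }

    names = list(all_scalars[0])
    draws = {
        name: np.array([np.array(s[name]) for s in all_scalars]) for name in names
    }
    latent_draws = {
        name: np.array([np.array(l[name]) for l in all_latents])
        for name in ("nu0", "nu1", "logb", "frail")
    }
    summaries = _summaries(draws)
    diag = _diagnostics(draws, st)
    if not diag["ok"].all():
        bad = diag.index[~diag["ok"]].tolist()
        msg = f"marginal convergence diagnostics for: {bad}"
        if st.on_nonconvergence == "error":
            raise ConvergenceError(msg, diag)
        log.warning(msg)

    result = PosteriorResult(
        draws=draws,
        latent_draws=latent_draws,
        summaries=summaries,
        convergence=diag,
        accept_rates=acc_rates,
        spec=spec,
        settings=st,
        data=data,
    )
    result.dic = compute_dic(result)
    return result


class ConvergenceError(RuntimeError):
    """Raised when diagnostics fail and the settings demand failure."""

    def __init__(self, msg, diagnostics=None):
        super().__init__(msg)
        self.diagnostics = diagnostics


# --------------------------------------------------------------------------
# DIC


def _deviance(result: PosteriorResult, beta1, beta2, nu0, nu1, logb, frail,
              tau0, tau1, tau_b, rho, phi, sigma_e2) -> float:
    d = result.data
    ll = 0.0
    if d.y is not None:
        eta1 = d.X1 @ beta1 + nu0[d.pat] + nu1[d.pat] * d.tstd
        var = np.exp(logb)[d.pat] if result.spec.logb_active else sigma_e2
        ll += pln_marginal_loglik(d.y, eta1, var, nodes=result.settings.gh_nodes)
    if d.t is not None:
        w2 = tau0 * nu0 + tau1 * nu1 + tau_b * logb + frail
        eta2 = (d.X2 @ beta2 if len(d.surv_terms) else 0.0) + w2
        ll += weibull_loglik(d.t, d.delta, eta2, rho, phi)
    return -2.0 * ll


def compute_dic(result: PosteriorResult, max_draws: int | None = None) -> DicResult:
    """Conditional DIC: Dbar over draws, D_hat at posterior means, pD = Dbar - D_hat.

    The deviance conditions on the patient-level latent effects (plugged at
    posterior means for D_hat) with the visit-level perturbation integrated
    out by quadrature.  A negative pD is reported with a warning, not hidden.
    """
    d = result.data
    spec = result.spec
    chains, ndraw = next(iter(result.latent_draws.values())).shape[:2]
    total = chains * ndraw
    nmax = max_draws or result.settings.dic_draws
    idx = np.linspace(0, total - 1, min(nmax, total)).astype(int)

    def flat(name, default=0.0):
        if name in result.draws:
            return result.draws[name].reshape(-1)
        return np.full(total, default)

    b1 = (
        np.column_stack([flat(f"beta1:{t}") for t in d.long_terms])
        if d.y is not None
        else np.zeros((total, 0))
    )
    b2 = (
        np.column_stack([flat(f"beta2:{t}") for t in d.surv_terms])
        if (d.t is not None and d.surv_terms)
        else np.zeros((total, 0))
    )
    lat = {k: v.reshape(total, d.n) for k, v in result.latent_draws.items()}
    tau0, tau1 = flat("tau0"), flat("tau1")
    tau_b = flat("tau_b")
    rho, phi = flat("rho", 1.0), flat("phi", 1.0)
    se2 = flat("sigma_e2", 0.0)

    devs = [
        _deviance(
            result, b1[i], b2[i], lat["nu0"][i], lat["nu1"][i], lat["logb"][i],
            lat["frail"][i], tau0[i], tau1[i], tau_b[i], rho[i], phi[i], se2[i],
        )
        for i in idx
    ]
    dbar = float(np.mean(devs))
    dhat = _deviance(
        result, b1.mean(0), b2.mean(0), lat["nu0"].mean(0), lat["nu1"].mean(0),
        lat["logb"].mean(0), lat["frail"].mean(0), tau0.mean(), tau1.mean(),
        tau_b.mean(), rho.mean(), phi.mean(), se2.mean(),
    )
    p_d = dbar - dhat
    if p_d < 0:
        log.warning("negative effective parameter count pD = %.2f (DIC pathology)", p_d)
    return DicResult(dbar=dbar, dhat=dhat, p_d=p_d, dic=dbar + p_d)


# --------------------------------------------------------------------------
# ladder and hazard ratios


def run_ladder(
    longitudinal: pd.DataFrame,
    survival: pd.DataFrame,
    covariates: pd.DataFrame,
    long_terms: list[str],
    surv_terms: list[str],
    settings: McmcSettings | None = None,
    heterogeneous: bool = True,
    levels: tuple[str, ...] = LADDER_LEVELS,
    schedule: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fit the nested random-effects ladder and tabulate DIC per rung.

    Any failing rung is marked failed and the ladder continues; the
    smallest-DIC rung among the successes is flagged selected.
    """
    st = settings or McmcSettings()
    rows = []
    results = {}
    for i, level in enumerate(levels):
        spec = JointModelSpec(
            longitudinal_terms=long_terms,
            survival_terms=surv_terms,
            ladder_level=level,
            heterogeneous_variance=heterogeneous,
        )
        row = {"ladder_level": level, "status": "ok", "dic": np.nan,
               "dbar": np.nan, "p_d": np.nan}
        try:
            sub = McmcSettings(**{**st.__dict__, "seed": None if st.seed is None else st.seed + i})
            res = run_mcmc(longitudinal, survival, covariates, spec, sub, schedule=schedule)
            results[level] = res
            row.update(dic=res.dic.dic, dbar=res.dic.dbar, p_d=res.dic.p_d)
        except Exception as exc:  # keep the ladder going
            log.warning("ladder rung %s failed: %s", level, exc)
            row["status"] = f"failed: {exc}"
        rows.append(row)
    out = pd.DataFrame(rows)
    ok = out["status"] == "ok"
    out["selected"] = False
    if ok.any():
        out.loc[out.loc[ok, "dic"].idxmin(), "selected"] = True
    out.attrs["results"] = results
    return out


def hazard_ratio_table(result: PosteriorResult) -> pd.DataFrame:
    """Per-term hazard ratios: exp applied draw-wise, then summarised.

    Covers the survival coefficients and the association loadings; the 95%
    interval is the (2.5%, 97.5%) quantile pair of the exponentiated draws.
    """
    names = [k for k in result.draws if k.startswith("beta2:")]
    names += [k for k in ("tau0", "tau1", "tau_b") if k in result.draws]
    if not names:
        raise ValueError("posterior contains no survival coefficients")
    rows = []
    for name in names:
        hr = np.exp(result.stacked(name))
        lo, hi = np.quantile(hr, [0.025, 0.975])
        rows.append(
            {"term": name.removeprefix("beta2:"), "hr": hr.mean(),
             "hr_q2.5": lo, "hr_q97.5": hi}
        )
    return pd.DataFrame(rows).set_index("term")


def percent_change(coef: float) -> float:
    """Express a log-scale coefficient as a percent change: 100(e^b - 1)."""
    return 100.0 * (np.exp(coef) - 1.0)
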