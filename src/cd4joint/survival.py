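"""Separate time-to-default fits: Weibull / exponential PH and Cox PH.

The parametric models maximise the censored Weibull proportional-hazards
likelihood ``prod h(t_i)^delta_i S(t_i)`` with hazard
``h(t) = phi rho t^(rho-1) exp(x'beta)``; the exponential model is the
shape-one special case.  Discrete follow-up counts are treated as continuous
event times; the Cox fit (lifelines) uses Breslow tie handling.  A frailty
variant routes through the shared MCMC engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .criteria import FitCriteria
from .design import build_design
from .likelihoods import weibull_loglik

__all__ = [
    "SurvivalModelSpec",
    "SurvivalFit",
    "fit_parametric_survival",
    "fit_cox",
    "compare_survival_models",
]

log = logging.getLogger(__name__)


@dataclass
class SurvivalModelSpec:
    baseline: str = "weibull"  # weibull | exponential | cox
    fixed_effects: list[str] = field(default_factory=list)
    frailty: bool = False

    def __post_init__(self):
        if self.baseline not in ("weibull", "exponential", "cox"):
            raise ValueError("baseline must be weibull, exponential or cox")
        if self.baseline == "cox" and self.frailty:
            raise ValueError("frailty is only supported for parametric baselines")


@dataclass
class SurvivalFit:
    spec: SurvivalModelSpec
    coef: pd.DataFrame  # term, estimate, lower, upper
    shape: float | None  # rho (parametric only)
    shape_interval: tuple[float, float] | None
    scale: float | None  # phi (parametric only)
    frailty_var: float | None
    criteria: FitCriteria
    engine: str = "ml"

    @property
    def hazard_ratios(self) -> pd.DataFrame:
        hr = self.coef.copy()
        for c in ("estimate", "lower", "upper"):
            hr[c] = np.exp(hr[c])
        return hr.rename(columns={"estimate": "hr", "lower": "hr_lower", "upper": "hr_upper"})

    @property
    def hazard_decreasing(self) -> bool | None:
        """Verdict on hazard monotonicity: decreasing default rate iff rho < 1."""
        if self.shape is None:
            return None
        return bool(self.shape < 1.0)

    def hazard(self, t: np.ndarray, x_eta: float = 0.0) -> np.ndarray:
        """Fitted baseline-group hazard phi rho t^(rho-1) exp(x_eta)."""
        if self.shape is None:
            raise ValueError("hazard function available for parametric fits only")
        t = np.asarray(t, dtype=float)
        return self.scale * self.shape * t ** (self.shape - 1.0) * np.exp(x_eta)


def _weibull_negll(theta: np.ndarray, t, delta, X, fix_rho: float | None):
    if fix_rho is None:
        log_phi, log_rho = theta[0], theta[1]
        beta = theta[2:]
    else:
        log_phi, log_rho = theta[0], np.log(fix_rho)
        beta = theta[1:]
    eta = X @ beta if X is not None else 0.0
    return -weibull_loglik(t, delta, eta, np.exp(log_rho), np.exp(log_phi))


def _weibull_ml(t, delta, X, fix_rho: float | None = None) -> np.ndarray:
    """ML point estimate; returns [log_phi, (log_rho,) beta...]."""
    k = 0 if X is None else X.shape[1]
    x0 = np.zeros((1 if fix_rho is not None else 2) + k)
    # moment-ish start: exponential rate = events / total time
    rate = max(delta.sum(), 0.5) / t.sum()
    x0[0] = np.log(rate)
    res = optimize.minimize(
        _weibull_negll, x0, args=(t, delta, X, fix_rho), method="BFGS",
        options={"gtol": 1e-8, "maxiter": 500},
    )
    if not np.all(np.isfinite(res.x)):
        raise RuntimeError("Weibull likelihood maximisation failed")
    return res.x


def _num_hessian(f, x, h=1e-5):
    k = len(x)
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h * h)
    return H


def fit_parametric_survival(
    table: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    spec: SurvivalModelSpec | None = None,
    settings=None,
) -> SurvivalFit:
    """Fit the censored Weibull (or exponential) proportional-hazards model.

    ``table`` needs ``patient_id``, ``time`` (> 0) and ``event`` columns.
    With ``spec.frailty`` the model gains a patient-level log-normal frailty
    and is fitted by the shared MCMC engine instead of maximum likelihood.
    A shape estimate below one is reported as a decreasing default rate.
    """
    spec = spec or SurvivalModelSpec()
    t = table["time"].to_numpy(dtype=float)
    delta = table["event"].to_numpy(dtype=float)
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    if delta.sum() < 1:
        raise ValueError("at least one observed event is required")
    X = None
    terms = [s for s in spec.fixed_effects if s != "intercept"]
    if terms:
        if covariates is None:
            raise ValueError("covariates table required for fixed effects")
        cov = covariates.set_index("patient_id").loc[table["patient_id"]].reset_index()
        X = build_design(cov, terms)

    if spec.frailty:
        return _fit_parametric_mcmc(table, covariates, spec, terms, settings)

    fix_rho = 1.0 if spec.baseline == "exponential" else None
    theta = _weibull_ml(t, delta, X, fix_rho=fix_rho)
    negll = lambda th: _weibull_negll(th, t, delta, X, fix_rho)
    H = _num_hessian(negll, theta)
    try:
        cov_theta = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov_theta), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(theta), np.nan)

    log_phi = theta[0]
    if fix_rho is None:
        log_rho, beta = theta[1], theta[2:]
        se_logrho, se_beta = se[1], se[2:]
    else:
        log_rho, beta = 0.0, theta[1:]
        se_logrho, se_beta = 0.0, se[1:]
    rho = float(np.exp(log_rho))
    shape_iv = (float(np.exp(log_rho - 1.96 * se_logrho)), float(np.exp(log_rho + 1.96 * se_logrho)))

    coef = pd.DataFrame(
        {
            "term": terms,
            "estimate": beta,
            "lower": beta - 1.96 * se_beta,
            "upper": beta + 1.96 * se_beta,
        }
    ).set_index("term")

    loglik = -negll(theta)
    k = len(theta)
    eta = X @ beta if X is not None else 0.0
    Lam = np.exp(log_phi) * t**rho * np.exp(eta)
    pearson = float(np.sum((delta - Lam) ** 2 / Lam))  # counting-process residuals
    crit = FitCriteria(loglik=loglik, k=k, nobs=len(t), pearson_chi2=pearson, dof=len(t) - k)
    return SurvivalFit(
        spec=spec, coef=coef, shape=rho, shape_interval=shape_iv,
        scale=float(np.exp(log_phi)), frailty_var=None, criteria=crit,
    )


def _fit_parametric_mcmc(table, covariates, spec, terms, settings):
    from .joint import JointModelSpec, McmcSettings, run_mcmc

    st = settings or McmcSettings()
    jspec = JointModelSpec(
        survival_terms=terms,
        ladder_level="intercept_slope_frailty",
        include_longitudinal=False,
        heterogeneous_variance=False,
    )
    res = run_mcmc(None, table, covariates, jspec, st)
    s = res.summaries
    rows = [
        {"term": t_, "estimate": s.loc[f"beta2:{t_}", "mean"],
         "lower": s.loc[f"beta2:{t_}", "q2.5"], "upper": s.loc[f"beta2:{t_}", "q97.5"]}
        for t_ in terms
    ]
    coef = pd.DataFrame(rows).set_index("term") if rows else pd.DataFrame(
        columns=["estimate", "lower", "upper"]
    )
    rho = float(s.loc["rho", "mean"])
    dic = res.dic
    crit = FitCriteria(loglik=-dic.dhat / 2.0, k=int(round(dic.p_d)), nobs=len(table),
                       note="posterior (DIC-based) criteria")
    return SurvivalFit(
        spec=spec, coef=coef, shape=rho,
        shape_interval=(float(s.loc["rho", "q2.5"]), float(s.loc["rho", "q97.5"])),
        scale=float(s.loc["phi", "mean"]) if "phi" in s.index else 1.0,
        frailty_var=float(s.loc["sigma_nu2", "mean"]) if "sigma_nu2" in s.index else None,
        criteria=crit, engine="mcmc",
    )


def fit_cox(
    table: pd.DataFrame,
    covariates: pd.DataFrame,
    fixed_effects: list[str],
    settings=None,
) -> SurvivalFit:
    """Cox proportional hazards by Breslow partial likelihood (lifelines).

    Zero-variance covariate columns carry no information and are reported
    with coefficient 0.  The BIC cell is flagged approximate: it is computed
    from the partial likelihood with the event count as sample size.
    """
    from lifelines import CoxPHFitter

    terms = [s for s in fixed_effects if s != "intercept"]
    if not terms:
        raise ValueError("the Cox model requires at least one covariate")
    if table["event"].sum() < 1:
        raise ValueError("at least one observed event is required")
    cov = covariates.set_index("patient_id").loc[table["patient_id"]].reset_index()
    X = build_design(cov, terms)
    df = pd.DataFrame(X, columns=terms)
    const = [c for c in terms if df[c].nunique() <= 1]
    fit_terms = [c for c in terms if c not in const]
    if const:
        log.warning("constant covariates carry no information: %s", const)
    df["time"] = table["time"].to_numpy(dtype=float)
    df["event"] = table["event"].to_numpy(dtype=int)

    rows = []
    if fit_terms:
        cph = CoxPHFitter()
        try:
            cph.fit(df[fit_terms + ["time", "event"]], duration_col="time", event_col="event")
        except Exception as exc:
            raise RuntimeError(f"Cox partial-likelihood maximisation failed: {exc}") from exc
        summ = cph.summary
        for term in fit_terms:
            rows.append(
                {"term": term, "estimate": summ.loc[term, "coef"],
                 "lower": summ.loc[term, "coef lower 95%"],
                 "upper": summ.loc[term, "coef upper 95%"]}
            )
        loglik = float(cph.log_likelihood_)
        k = len(fit_terms)
    else:
        loglik, k = 0.0, 0
    for term in const:
        rows.append({"term": term, "estimate": 0.0, "lower": 0.0, "upper": 0.0})
    coef = pd.DataFrame(rows).set_index("term").loc[terms]

    n_events = int(table["event"].sum())
    crit = FitCriteria(
        loglik=loglik, k=k, nobs=max(n_events, 1),
        note="partial likelihood; BIC approximate; Pearson chi-square unavailable",
    )
    return SurvivalFit(
        spec=SurvivalModelSpec(baseline="cox", fixed_effects=terms),
        coef=coef, shape=None, shape_interval=None, scale=None,
        frailty_var=None, criteria=crit, engine="partial-likelihood",
    )


def compare_survival_models(fits: dict[str, SurvivalFit]) -> pd.DataFrame:
    """Smaller-is-better criteria table across >= 2 fits.

    Rows are criteria (AIC, BIC, Pearson chi2/df); the winner per criterion is
    named, unavailable cells stay missing, and criterion disagreements are
    flagged rather than silently resolved.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    rows = []
    for crit_name in ("aic", "bic", "pearson_ratio"):
        row: dict[str, object] = {"criterion": crit_name}
        vals = {}
        for name, fit in fits.items():
            v = getattr(fit.criteria, crit_name)
            row[name] = v
            if v is not None and np.isfinite(v):
                vals[name] = v
        if vals:
            best = min(vals.values())
            winners = sorted(k for k, v in vals.items() if np.isclose(v, best))
            row["winner"] = "tie: " + ", ".join(winners) if len(winners) > 1 else winners[0]
        else:
            row["winner"] = "unavailable"
        rows.append(row)
    out = pd.DataFrame(rows).set_index("criterion")
    decided = [w for w in out["winner"] if w != "unavailable" and not str(w).startswith("tie")]
    out.attrs["disagreement"] = len(set(decided)) > 1
    if out.attrs["disagreement"]:
        log.warning("criteria disagree on the preferred survival model: %s", decided)
    return out
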