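"""Separate longitudinal fits: overdispersion diagnosis and count GLMMs.

The CD4 change series is an overdispersed count outcome; the candidate
families are the Poisson-log-normal (the generative counterpart of a
quasi-Poisson fit: a conditional Poisson with a normal perturbation on the
log mean) with either a common or a patient-specific perturbation variance,
and the mean/overdispersion negative binomial (variance mu + alpha mu^2).
Mixed-model fits run through the shared Bayesian MCMC engine; the negative
binomial and the no-random-effects Poisson-log-normal are maximum-likelihood
fits (the latter marginalised by Gauss-Hermite quadrature).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .criteria import FitCriteria
from .design import build_design, coded_time, default_schedule
from .likelihoods import pln_marginal_loglik

__all__ = [
    "LongitudinalModelSpec",
    "LongitudinalFit",
    "compute_cd4_change",
    "mean_variance_profile",
    "fit_longitudinal",
    "compare_count_families",
]

log = logging.getLogger(__name__)

FAMILIES = (
    "poisson_lognormal_homogeneous",
    "poisson_lognormal_heterogeneous",
    "negative_binomial",
)


@dataclass
class LongitudinalModelSpec:
    family: str = "poisson_lognormal_heterogeneous"
    fixed_effects: list[str] = field(default_factory=lambda: ["intercept", "time"])
    random_effects: list[str] = field(default_factory=lambda: ["intercept", "slope"])

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        bad = set(self.random_effects) - {"intercept", "slope"}
        if bad:
            raise ValueError(f"unknown random effects: {sorted(bad)}")
        if "slope" in self.random_effects and "intercept" not in self.random_effects:
            raise ValueError("a random slope requires the random intercept")
        if self.family == "poisson_lognormal_heterogeneous" and not self.random_effects:
            raise ValueError("the heterogeneous family requires at least the random intercept")


@dataclass
class LongitudinalFit:
    spec: LongitudinalModelSpec
    coef: pd.DataFrame  # term, estimate, lower, upper
    varcomps: dict[str, float]
    criteria: FitCriteria
    per_patient_effects: pd.DataFrame | None
    engine: str
    convergence: pd.DataFrame | None = None
    posterior: object | None = None  # PosteriorResult for MCMC fits


def compute_cd4_change(counts) -> dict:
    """Per-patient change series from ordered CD4 count series.

    ``counts`` maps patient id -> ordered mapping/Series of visit_index ->
    observed count (or a long DataFrame with patient_id/visit_index/
    cd4_count).  The change at visit j is count_j - count_{j-1} and is only
    defined when both adjacent visits were observed (no imputation across
    gaps).  Patients with fewer than two observed counts are excluded with a
    logged warning.
    """
    if isinstance(counts, pd.DataFrame):
        obs = counts[counts.get("observed", True) & counts["cd4_count"].notna()]
        series = {
            pid: g.set_index("visit_index")["cd4_count"]
            for pid, g in obs.groupby("patient_id")
        }
    else:
        series = {pid: pd.Series(dict(s)) for pid, s in counts.items()}
    out = {}
    for pid, s in series.items():
        s = s.sort_index()
        if len(s) < 2:
            log.warning("patient %r excluded: fewer than two observed counts", pid)
            continue
        idx = s.index.to_numpy()
        vals = s.to_numpy(dtype=float)
        adjacent = np.diff(idx) == 1
        changes = pd.Series(
            (vals[1:] - vals[:-1])[adjacent], index=idx[1:][adjacent], dtype=float
        )
        out[pid] = changes
    return out


def mean_variance_profile(table: pd.DataFrame, min_obs: int = 2) -> pd.DataFrame:
    """Per-visit mean and sample SD of observed changes plus the verdict.

    The overdispersion verdict per visit is sample variance > mean (the
    visual mean-variance check for a count outcome).  Visits with fewer than
    ``min_obs`` observed changes are dropped with a log note.
    """
    obs = table[table.get("observed", True) & table["cd4_change"].notna()]
    rows = []
    for j, g in obs.groupby("visit_index"):
        x = g["cd4_change"].to_numpy(dtype=float)
        if len(x) < min_obs:
            log.info("visit %s dropped from profile (%d observations)", j, len(x))
            continue
        mean = x.mean()
        sd = x.std(ddof=1)
        rows.append(
            {"visit_index": j, "n": len(x), "mean": mean, "sd": sd,
             "overdispersed": bool(sd**2 > mean)}
        )
    return pd.DataFrame(rows).set_index("visit_index")


# --------------------------------------------------------------------------
# maximum-likelihood engines


def _pln_ml(y, X, fix_sigma2: float | None = None, nodes: int = 25):
    """ML fit of the marginal Poisson-log-normal model (no patient effects).

    Returns (beta, sigma2, loglik, cov_beta).  ``fix_sigma2=0`` reduces to a
    plain log-link Poisson regression.
    """
    k = X.shape[1]

    def negll(theta):
        beta = theta[:k]
        s2 = fix_sigma2 if fix_sigma2 is not None else np.exp(theta[k])
        return -pln_marginal_loglik(y, X @ beta, s2, nodes=nodes)

    x0 = np.zeros(k + (0 if fix_sigma2 is not None else 1))
    if np.allclose(X[:, 0], 1.0):  # start the intercept at the crude log mean
        x0[0] = np.log(max(y.mean(), 0.1))
    res = optimize.minimize(negll, x0, method="BFGS", options={"gtol": 1e-9, "maxiter": 1000})
    beta = res.x[:k]
    s2 = fix_sigma2 if fix_sigma2 is not None else float(np.exp(res.x[k]))
    from .survival import _num_hessian

    H = _num_hessian(negll, res.x)
    try:
        cov = np.linalg.inv(H)[:k, :k]
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
    return beta, s2, -res.fun, cov


def _fit_negative_binomial(y, X, terms):
    import statsmodels.api as sm

    model = sm.NegativeBinomial(y, X)
    with np.errstate(all="ignore"):
        res = model.fit(disp=0, maxiter=200)
    beta = res.params[: X.shape[1]]
    alpha = float(res.params[-1])
    mu = np.exp(np.clip(X @ beta, -30, 30))
    var = mu + alpha * mu**2
    pearson = float(np.sum((y - mu) ** 2 / var))
    k = X.shape[1] + 1
    crit = FitCriteria(loglik=float(res.llf), k=k, nobs=len(y),
                       pearson_chi2=pearson, dof=len(y) - k)
    ci = res.conf_int()
    ci = np.asarray(ci)
    coef = pd.DataFrame(
        {"term": terms, "estimate": beta, "lower": ci[: len(terms), 0],
         "upper": ci[: len(terms), 1]}
    ).set_index("term")
    return coef, {"alpha": alpha}, crit


def fit_longitudinal(
    table: pd.DataFrame,
    covariates: pd.DataFrame,
    spec: LongitudinalModelSpec,
    settings=None,
    schedule: np.ndarray | None = None,
) -> LongitudinalFit:
    """Fit one longitudinal count model to the observed change rows.

    Engines: Bayesian MCMC (the shared joint-model sampler with the survival
    submodel switched off) for the Poisson-log-normal families with random
    effects; maximum likelihood for the negative binomial and for
    Poisson-log-normal fits without random effects.  ``settings`` is an
    :class:`~cd4joint.joint.McmcSettings` for the MCMC path; for the ML path
    an object carrying a ``fix_sigma_e2`` attribute pins the perturbation
    variance (0 gives the plain log-link Poisson regression limit).
    """
    from .joint import JointModelSpec, McmcSettings, run_mcmc

    obs = table[table.get("observed", True) & table["cd4_change"].notna()]
    counts = obs.groupby("patient_id").size()
    few = counts[counts < 1].index
    if len(few):
        log.warning("patients without observed changes are ignored: %s", list(few)[:5])
    missing = set(obs["patient_id"]) - set(covariates["patient_id"])
    if missing:
        raise ValueError("covariate table does not cover all patients")

    if schedule is None:
        schedule = default_schedule()
    y = obs["cd4_change"].to_numpy(dtype=float)
    ids = covariates["patient_id"].to_numpy()
    index = pd.Series(np.arange(len(ids)), index=ids)
    pat = index[obs["patient_id"]].to_numpy()
    tstd = coded_time(obs["visit_index"].to_numpy(dtype=float), len(schedule))
    X = build_design(covariates, spec.fixed_effects, time_std=tstd, row_patient=pat)

    if spec.family == "negative_binomial":
        coef, varcomps, crit = _fit_negative_binomial(y, X, spec.fixed_effects)
        return LongitudinalFit(spec, coef, varcomps, crit, None, engine="ml")

    if not spec.random_effects:
        fix = getattr(settings, "fix_sigma_e2", None) if settings is not None else None
        beta, s2, ll, cov = _pln_ml(y, X, fix_sigma2=fix)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        coef = pd.DataFrame(
            {"term": spec.fixed_effects, "estimate": beta,
             "lower": beta - 1.96 * se, "upper": beta + 1.96 * se}
        ).set_index("term")
        k = X.shape[1] + (0 if fix is not None else 1)
        mu = np.exp(np.clip(X @ beta + s2 / 2.0, -30, 30))
        pearson = float(np.sum((y - mu) ** 2 / mu))
        crit = FitCriteria(loglik=ll, k=k, nobs=len(y), pearson_chi2=pearson, dof=len(y) - k)
        return LongitudinalFit(spec, coef, {"sigma_e2": s2}, crit, None, engine="ml")

    # MCMC path through the shared engine, survival submodel off
    st = settings or McmcSettings()
    heterogeneous = spec.family == "poisson_lognormal_heterogeneous"
    ladder = "intercept_slope_frailty" if "slope" in spec.random_effects else "random_intercept"
    jspec = JointModelSpec(
        longitudinal_terms=spec.fixed_effects,
        ladder_level=ladder,
        heterogeneous_variance=heterogeneous,
        include_survival=False,
    )
    res = run_mcmc(table, None, covariates, jspec, st, schedule=schedule)
    s = res.summaries
    rows = [
        {"term": t_, "estimate": s.loc[f"beta1:{t_}", "mean"],
         "lower": s.loc[f"beta1:{t_}", "q2.5"], "upper": s.loc[f"beta1:{t_}", "q97.5"]}
        for t_ in spec.fixed_effects
    ]
    coef = pd.DataFrame(rows).set_index("term")
    varcomps = {}
    for name in ("var_nu0", "var_nu1", "cov_nu01", "corr_nu01", "sigma_b2", "sigma_e2"):
        if name in s.index:
            varcomps[name] = float(s.loc[name, "mean"])

    # criteria at posterior means, conditional on estimated random effects
    beta1 = np.array([s.loc[f"beta1:{t_}", "mean"] for t_ in spec.fixed_effects])
    nu0 = res.latent_mean("nu0")
    nu1 = res.latent_mean("nu1")
    logb = res.latent_mean("logb")
    eta = X @ beta1 + nu0[pat] + nu1[pat] * tstd
    var = np.exp(logb)[pat] if heterogeneous else varcomps.get("sigma_e2", 0.0)
    ll = pln_marginal_loglik(y, eta, var, nodes=st.gh_nodes)
    mu = np.exp(np.clip(eta + (np.exp(logb)[pat] if heterogeneous else var) / 2.0, -30, 30))
    pearson = float(np.sum((y - mu) ** 2 / mu))
    k = len(spec.fixed_effects) + len(varcomps)
    crit = FitCriteria(
        loglik=ll, k=k, nobs=len(y), pearson_chi2=pearson, dof=len(y) - k,
        note="log-likelihood at posterior means, conditional on random effects",
    )
    per_patient = pd.DataFrame(
        {"patient_id": ids, "nu0": nu0, "nu1": nu1, "log_b": logb}
    )
    return LongitudinalFit(
        spec, coef, varcomps, crit, per_patient, engine="mcmc",
        convergence=res.convergence, posterior=res,
    )


def compare_count_families(
    table: pd.DataFrame,
    covariates: pd.DataFrame,
    fixed_effects: list[str] | None = None,
    schedule: np.ndarray | None = None,
    settings=None,
    random_effects: bool = True,
) -> pd.DataFrame:
    """Quasi-Poisson(-log-normal) versus negative binomial criteria table.

    The log-normal side is the mixed Poisson-log-normal fit (MCMC engine,
    patient intercept and slope); the negative binomial is a plain ML fit —
    the two candidate treatments of overdispersion in the source analysis.
    ``random_effects=False`` compares the marginal (visit-level only)
    families instead, both by maximum likelihood.  Criteria are ranked
    smaller-is-better on AIC, BIC and Pearson chi2/df; ties are declared and
    criterion disagreements flagged rather than resolved.
    """
    from .joint import McmcSettings

    fixed_effects = fixed_effects or ["intercept", "time"]
    if random_effects:
        spec_pln = LongitudinalModelSpec(
            family="poisson_lognormal_heterogeneous", fixed_effects=fixed_effects,
            random_effects=["intercept", "slope"],
        )
        settings = settings or McmcSettings(
            chains=1, iterations=1500, burn=800, thin=2, seed=0, adapt_interval=25
        )
    else:
        spec_pln = LongitudinalModelSpec(
            family="poisson_lognormal_homogeneous", fixed_effects=fixed_effects,
            random_effects=[],
        )
    spec_nb = LongitudinalModelSpec(
        family="negative_binomial", fixed_effects=fixed_effects, random_effects=[]
    )
    try:
        fit_pln = fit_longitudinal(table, covariates, spec_pln, settings=settings,
                                   schedule=schedule)
        fit_nb = fit_longitudinal(table, covariates, spec_nb, schedule=schedule)
    except Exception as exc:
        raise RuntimeError(f"family comparison aborted: {exc}") from exc

    rows = []
    for crit_name in ("aic", "bic", "pearson_ratio"):
        a = getattr(fit_pln.criteria, crit_name)
        b = getattr(fit_nb.criteria, crit_name)
        if np.isclose(a, b):
            winner = "tie"
            log.info("criterion %s is a tie", crit_name)
        else:
            winner = "poisson_lognormal" if a < b else "negative_binomial"
        rows.append(
            {"criterion": crit_name, "poisson_lognormal": a,
             "negative_binomial": b, "winner": winner}
        )
    out = pd.DataFrame(rows).set_index("criterion")
    decided = set(w for w in out["winner"] if w != "tie")
    out.attrs["disagreement"] = len(decided) > 1
    out.attrs["fits"] = {"poisson_lognormal": fit_pln, "negative_binomial": fit_nb}
    if out.attrs["disagreement"]:
        log.warning("criteria disagree on the preferred count family")
    return out
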