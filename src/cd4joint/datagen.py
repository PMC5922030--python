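"""Synthetic cohort generator for the joint CD4-change / time-to-default model.

Emulates the structure of a HAART cohort: baseline covariates drawn from the
reference cohort's marginals, correlated patient random effects, patient
specific log-normal dispersion, Poisson counts of the per-visit CD4 change on
a log link, Weibull default times driven by the shared latent term, an
administrative censoring horizon, and MCAR dropout.  All generators are pure
functions of their arguments and a seed.

The per-visit CD4 *change* is the modelled count: the first on-treatment
visit is the reference measurement (no change row), and the CD4 count series
is the cumulative sum of the generated changes on top of that reference.
Changes are therefore non-negative by construction, matching the count-model
treatment of the outcome; real CD4 changes can fall, which this generator
does not emulate (see docs/methods.md).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import build_design, coded_time, default_schedule
from .params import TrueParameters, continuous_marginals, table_marginals

__all__ = [
    "generate_covariates",
    "generate_latent_effects",
    "generate_longitudinal",
    "generate_survival",
    "truncate_longitudinal",
    "apply_mcar",
    "simulate_cohort",
    "Cohort",
    "write_cohort",
    "read_cohort",
]

log = logging.getLogger(__name__)

_CAT_VARS = set(table_marginals())
_CONT_VARS = set(continuous_marginals())


def _lognormal_from_quartiles(med: float, q1: float, q3: float):
    """(mu, sigma) of a log-normal matching the given median and quartiles."""
    mu = np.log(med)
    # Q3/Q1 span = 2 * 0.6745 sigma on the log scale
    sigma = (np.log(q3) - np.log(q1)) / 1.349
    return mu, sigma


def generate_covariates(
    n: int,
    marginals: dict[str, dict[str, float]] | None = None,
    seed: int | None = None,
    exact: bool = False,
) -> pd.DataFrame:
    """Draw ``n`` baseline covariate profiles from category marginals.

    Parameters
    ----------
    n
        Cohort size (>= 1).
    marginals
        Per-variable category->frequency maps; defaults to the reference
        cohort's marginals.  Partial overrides are allowed (unlisted
        variables keep their defaults).
    exact
        When True, categorical counts are allocated deterministically by
        largest remainder (then shuffled) instead of sampled, so empirical
        counts equal ``round(n * freq)`` up to the remainder rule.

    Continuous covariates (age, weight, baseline CD4) are log-normal with
    median and quartiles matched to the cohort table; age is resampled to
    respect the adult-cohort floor of 18 years.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = table_marginals()
    if marginals:
        for var, freqs in marginals.items():
            if var not in _CAT_VARS:
                raise ValueError(f"unknown categorical variable {var!r}")
            levels = set(base[var])
            extra = set(freqs) - levels
            if extra:
                raise ValueError(f"unknown levels for {var!r}: {sorted(extra)}")
            merged = dict(base[var])
            merged.update(freqs)
            # renormalise remaining mass over unspecified levels
            spec_mass = sum(freqs.values())
            rest = [lv for lv in merged if lv not in freqs]
            rest_mass = sum(base[var][lv] for lv in rest)
            if rest and rest_mass > 0:
                for lv in rest:
                    merged[lv] = base[var][lv] * (1.0 - spec_mass) / rest_mass
            base[var] = merged
    for var, freqs in base.items():
        total = sum(freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies for {var!r} sum to {total}, not 1")
        if any(f < 0 for f in freqs.values()):
            raise ValueError(f"negative frequency for {var!r}")

    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {"patient_id": np.arange(1, n + 1)}
    for var, freqs in base.items():
        levels = list(freqs)
        probs = np.array([freqs[lv] for lv in levels], dtype=float)
        if exact:
            raw = probs * n
            counts = np.floor(raw).astype(int)
            short = n - counts.sum()
            order = np.argsort(-(raw - counts))
            counts[order[:short]] += 1
            values = np.repeat(levels, counts)
            out[var] = rng.permutation(values)
        else:
            out[var] = rng.choice(levels, size=n, p=probs)

    cont = continuous_marginals()
    for var, spec in cont.items():
        mu, sigma = _lognormal_from_quartiles(spec["median"], spec["q1"], spec["q3"])
        x = rng.lognormal(mu, sigma, size=n)
        lo = spec["minimum"]
        bad = x < lo
        while bad.any():
            x[bad] = rng.lognormal(mu, sigma, size=int(bad.sum()))
            bad = x < lo
        out[var] = np.round(x, 1)
    df = pd.DataFrame(out)
    df["age"] = np.round(df["age"]).astype(float)
    return df


def generate_latent_effects(
    n: int, params: TrueParameters, seed: int | None = None
) -> pd.DataFrame:
    """Draw per-patient latent effects (nu0, nu1, log_b, frailty).

    (nu0, nu1) are jointly zero-mean with covariance ``Sigma_nu``; log b_i is
    N(0, sigma_b2); the frailty is N(0, sigma_nu2); all mutually independent
    of the covariates.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params.validate()
    rng = np.random.default_rng(seed)
    # eigen square root handles the semi-definite (zero-variance) edge
    vals, vecs = np.linalg.eigh(params.Sigma_nu)
    root = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None))) @ vecs.T
    nu = rng.standard_normal((n, 2)) @ root.T
    log_b = rng.normal(0.0, np.sqrt(params.sigma_b2), size=n)
    frailty = rng.normal(0.0, np.sqrt(params.sigma_nu2), size=n)
    return pd.DataFrame(
        {"nu0": nu[:, 0], "nu1": nu[:, 1], "log_b": log_b, "frailty": frailty}
    )


def generate_longitudinal(
    covariates: pd.DataFrame,
    effects: pd.DataFrame,
    params: TrueParameters,
    schedule: np.ndarray | None = None,
    seed: int | None = None,
    logmu_cap: float = 20.0,
) -> pd.DataFrame:
    """Generate the long-format CD4 table (one row per patient-visit).

    For visit j >= 2 of patient i the change count is drawn as::

        eps_ij ~ N(0, b_i)
        log mu_ij = x_ij' beta1 + nu0_i + nu1_i * t_j + eps_ij
        cd4_change_ij ~ Poisson(mu_ij)

    with t_j the centred visit index (one unit = one follow-up visit, the
    clock shared with the survival submodel).  The first visit carries
    the reference CD4 count (the baseline covariate) and no change.  Linear
    predictors beyond ``logmu_cap`` in magnitude are truncated with a logged
    warning.
    """
    if len(covariates) != len(effects):
        raise ValueError("one latent-effect row per covariate profile required")
    if schedule is None:
        schedule = default_schedule()
    schedule = np.asarray(schedule, dtype=float)
    if schedule.size == 0 or np.any(np.diff(schedule) <= 0):
        raise ValueError("schedule must be nonempty and strictly increasing")
    params.validate()
    rng = np.random.default_rng(seed)

    n = len(covariates)
    J = len(schedule)
    tcode = coded_time(np.arange(1, J + 1))

    terms = [t for t in params.beta1 if t != "time"]
    Xp = build_design(covariates, terms)  # (n, k)
    beta_p = np.array([params.beta1[t] for t in terms])
    beta_time = params.beta1.get("time", 0.0)
    eta_pat = Xp @ beta_p  # (n,)

    b = params.b_scale * np.exp(effects["log_b"].to_numpy())
    nu0 = effects["nu0"].to_numpy()
    nu1 = effects["nu1"].to_numpy()

    rows = []
    # first visit: reference measurement, no modelled change
    first_count = np.round(covariates["baseline_cd4"].to_numpy()).astype(int)
    counts = first_count.copy()
    rows.append(
        pd.DataFrame(
            {
                "patient_id": covariates["patient_id"].to_numpy(),
                "visit_index": 1,
                "visit_time": schedule[0],
                "cd4_count": counts.copy(),
                "cd4_change": np.nan,
                "observed": True,
            }
        )
    )
    n_capped = 0
    for j in range(1, J):
        eps = rng.normal(0.0, np.sqrt(b))
        logmu = eta_pat + beta_time * tcode[j] + nu0 + nu1 * tcode[j] + eps
        over = np.abs(logmu) > logmu_cap
        n_capped += int(over.sum())
        logmu = np.clip(logmu, -logmu_cap, logmu_cap)
        change = rng.poisson(np.exp(logmu))
        counts = counts + change
        rows.append(
            pd.DataFrame(
                {
                    "patient_id": covariates["patient_id"].to_numpy(),
                    "visit_index": j + 1,
                    "visit_time": schedule[j],
                    "cd4_count": counts.copy(),
                    "cd4_change": change.astype(float),
                    "observed": True,
                }
            )
        )
    if n_capped:
        log.warning("truncated %d linear predictors at |log mu| = %g", n_capped, logmu_cap)
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["patient_id", "visit_index"], ignore_index=True)


def generate_survival(
    covariates: pd.DataFrame,
    effects: pd.DataFrame,
    params: TrueParameters,
    max_followups: int = 20,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw time-to-default (in follow-up visits) from the Weibull PH model.

    The log hazard is ``x_i' beta2 + W2_i`` with the shared latent term
    ``W2_i = tau0 nu0 + tau1 nu1 + tau_b log b_i + frailty`` placed inside
    the exponent (multiplicative frailty).  Event times are drawn by inverse
    CDF; times beyond ``max_followups`` are administratively censored there.
    """
    if max_followups < 1:
        raise ValueError("max_followups must be >= 1")
    if len(covariates) != len(effects):
        raise ValueError("one latent-effect row per covariate profile required")
    params.validate()
    rng = np.random.default_rng(seed)
    terms = [t for t in params.beta2 if t != "time"]
    X2 = build_design(covariates, terms)
    beta2 = np.array([params.beta2[t] for t in terms])
    tau0, tau1 = params.tau
    w2 = (
        tau0 * effects["nu0"].to_numpy()
        + tau1 * effects["nu1"].to_numpy()
        + params.tau_b * effects["log_b"].to_numpy()
        + effects["frailty"].to_numpy()
    )
    eta = (X2 @ beta2 if terms else np.zeros(len(covariates))) + w2
    u = rng.uniform(size=len(covariates))
    t_raw = (-np.log(u) / (params.phi * np.exp(eta))) ** (1.0 / params.rho)
    event = t_raw <= max_followups
    t = np.where(event, t_raw, float(max_followups))
    return pd.DataFrame(
        {
            "patient_id": covariates["patient_id"].to_numpy(),
            "time": t,
            "event": event.astype(int),
        }
    )


def truncate_longitudinal(
    longitudinal: pd.DataFrame, survival: pd.DataFrame
) -> pd.DataFrame:
    """Drop longitudinal records after each patient's default/censoring time."""
    tmap = survival.set_index("patient_id")["time"]
    t = longitudinal["patient_id"].map(tmap)
    keep = longitudinal["visit_index"] <= t
    return longitudinal.loc[keep].reset_index(drop=True)


def apply_mcar(
    longitudinal: pd.DataFrame, miss_prob: float, seed: int | None = None
) -> pd.DataFrame:
    """Flag post-baseline records missing completely at random.

    Each visit beyond the first is independently marked unobserved with
    probability ``miss_prob`` (independent of every outcome and covariate);
    the baseline visit is never removed.  Unobserved rows keep their place in
    the table with masked outcome values.
    """
    if not (0.0 <= miss_prob < 1.0):
        raise ValueError("miss_prob must lie in [0, 1)")
    out = longitudinal.copy()
    if miss_prob == 0.0:
        return out
    rng = np.random.default_rng(seed)
    eligible = out["visit_index"] > 1
    drop = eligible & (rng.uniform(size=len(out)) < miss_prob)
    out.loc[drop, "observed"] = False
    out.loc[drop, ["cd4_count", "cd4_change"]] = np.nan
    return out


@dataclass
class Cohort:
    """A complete simulated cohort plus its generative truth."""

    covariates: pd.DataFrame
    longitudinal: pd.DataFrame
    survival: pd.DataFrame
    effects: pd.DataFrame
    params: TrueParameters
    schedule: np.ndarray


def simulate_cohort(
    n: int,
    params: TrueParameters | None = None,
    schedule: np.ndarray | None = None,
    max_followups: int = 20,
    miss_prob: float = 0.1,
    seed: int | None = None,
    marginals: dict | None = None,
) -> Cohort:
    """Full generation pipeline: covariates -> latents -> outcomes -> dropout."""
    from .params import table_preset

    if params is None:
        params = table_preset()
    if schedule is None:
        schedule = default_schedule(max_followups)
    ss = np.random.SeedSequence(seed)
    s_cov, s_lat, s_long, s_surv, s_miss = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)
    ]
    cov = generate_covariates(n, marginals=marginals, seed=s_cov)
    eff = generate_latent_effects(n, params, seed=s_lat)
    long = generate_longitudinal(cov, eff, params, schedule=schedule, seed=s_long)
    surv = generate_survival(cov, eff, params, max_followups=max_followups, seed=s_surv)
    long = truncate_longitudinal(long, surv)
    long = apply_mcar(long, miss_prob, seed=s_miss)
    return Cohort(cov, long, surv, eff, params, np.asarray(schedule, dtype=float))


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write covariates.csv, longitudinal.csv and survival.csv (empty = missing)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.covariates.to_csv(outdir / "covariates.csv", index=False)
    cohort.longitudinal.to_csv(outdir / "longitudinal.csv", index=False)
    cohort.survival.to_csv(outdir / "survival.csv", index=False)


def read_cohort(indir: str | Path):
    """Read the three-CSV schema; returns (covariates, longitudinal, survival)."""
    indir = Path(indir)
    cov = pd.read_csv(indir / "covariates.csv")
    long = pd.read_csv(indir / "longitudinal.csv")
    surv = pd.read_csv(indir / "survival.csv")
    if "observed" in long.columns:
        long["observed"] = long["observed"].astype(bool)
    return cov, long, surv
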