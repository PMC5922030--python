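"""Missingness diagnostics and descriptive summaries.

The MCAR check fits a logistic regression of the per-visit missingness
indicator (coded 0 = missing, 1 = not missing) on baseline covariates, the
follow-up time, and an indicator of whether the previous observed CD4 count
rose; under MCAR no predictor should be informative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .design import build_design
from .params import continuous_marginals, table_marginals

__all__ = [
    "build_missingness_records",
    "mcar_check",
    "McarReport",
    "descriptive_table",
    "DescriptiveSummary",
]

log = logging.getLogger(__name__)

#: Default covariate set of the missingness model.
MCAR_TERMS = ["age", "male", "rural", "with_partner"]


def _round_half_up(x: float, digits: int = 1) -> float:
    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def build_missingness_records(
    longitudinal: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """One row per post-baseline scheduled visit with the missingness code.

    ``missing`` follows the 0 = missing / 1 = not-missing coding.  The rise
    indicator ``rise`` is 1 when the two most recent *observed* counts
    before the visit increased; rows where it is undefined (fewer than two
    prior observed counts) are dropped from the logistic fit.
    """
    cov = covariates.set_index("patient_id")
    d = longitudinal.sort_values(["patient_id", "visit_index"]).reset_index(drop=True)
    observed = d.get("observed", pd.Series(True, index=d.index)).astype(bool)
    # rise at an observed visit: its count exceeds the previous observed count
    o = d[observed & d["cd4_count"].notna()]
    prev_count = o.groupby("patient_id")["cd4_count"].shift(1)
    rise_src = (o["cd4_count"] > prev_count).astype(float).where(prev_count.notna())
    d["_rise_src"] = rise_src
    # for each row: the rise status of the most recent observed visit before it
    d["rise"] = d.groupby("patient_id")["_rise_src"].transform(
        lambda s: s.shift(1).ffill()
    )
    rec = d.loc[d["visit_index"] > 1,
                ["patient_id", "visit_index", "visit_time", "rise"]].copy()
    rec["missing"] = observed.loc[rec.index].astype(int)  # 1 = not missing
    if rec.empty:
        return rec
    rec = rec.reset_index(drop=True)
    c = cov.loc[rec["patient_id"]]
    rec["age"] = c["age"].to_numpy()
    rec["male"] = (c["sex"] == "male").to_numpy(float)
    rec["rural"] = (c["residence"] == "rural").to_numpy(float)
    rec["with_partner"] = (c["marital"] == "with_partner").to_numpy(float)
    return rec


@dataclass
class McarReport:
    table: pd.DataFrame  # term, estimate, se, p, p_adjusted
    alpha: float
    correction: str
    mcar_consistent: bool
    note: str = ""


def mcar_check(
    longitudinal: pd.DataFrame,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    include_rise: bool = True,
) -> McarReport:
    """Logistic-regression MCAR diagnostic.

    Fits ``P(not missing)`` on age, follow-up time, sex, residence, marital
    status and (optionally) the previous-count rise indicator.  The verdict
    is "consistent with MCAR" iff every non-intercept term is insignificant
    at ``alpha`` after the configured family-wise correction (``bonferroni``
    by default; ``none`` mirrors an uncorrected per-term read-out).  On
    complete separation the fit falls back to a ridge-penalised likelihood
    with a logged note.
    """
    import statsmodels.api as sm

    if correction not in ("bonferroni", "none"):
        raise ValueError("correction must be 'bonferroni' or 'none'")
    rec = build_missingness_records(longitudinal, covariates)
    if rec.empty or rec["missing"].nunique() < 2:
        raise ValueError("need at least one missing and one observed record")
    terms = MCAR_TERMS + ["visit_time"] + (["rise"] if include_rise else [])
    rec = rec.dropna(subset=[t for t in terms if t in rec.columns])
    ycol = rec["missing"].to_numpy(float)
    X = np.column_stack([np.ones(len(rec))] + [rec[t].to_numpy(float) for t in terms])
    names = ["intercept"] + terms

    note = ""
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(ycol, X).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(res.bse)):
            raise np.linalg.LinAlgError("non-finite standard errors")
        est, se, pvals = res.params, res.bse, res.pvalues
    except Exception as exc:
        note = f"penalized-likelihood fallback (complete separation suspected: {exc})"
        log.warning(note)
        est, se, pvals = _penalized_logit(ycol, X)

    n_tests = len(terms)
    padj = np.minimum(pvals * (n_tests if correction == "bonferroni" else 1.0), 1.0)
    table = pd.DataFrame(
        {"term": names, "estimate": est, "se": se, "p": pvals, "p_adjusted": padj}
    ).set_index("term")
    body = table.drop(index="intercept")
    verdict = bool((body["p_adjusted"] > alpha).all())
    return McarReport(table=table, alpha=alpha, correction=correction,
                      mcar_consistent=verdict, note=note)


def _penalized_logit(y, X, lam: float = 1e-3):
    """Ridge-penalised logistic fit with Wald-style SEs from the penalised Hessian."""
    from scipy import optimize
    from scipy.special import expit, log_expit
    from scipy.stats import norm

    def negll(beta):
        eta = X @ beta
        return -(np.sum(y * log_expit(eta) + (1 - y) * log_expit(-eta))) + lam * np.sum(beta**2)

    res = optimize.minimize(negll, np.zeros(X.shape[1]), method="BFGS")
    beta = res.x
    p = expit(X @ beta)
    W = p * (1 - p)
    H = X.T @ (X * W[:, None]) + 2 * lam * np.eye(X.shape[1])
    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2 * norm.sf(np.abs(z))
    return beta, se, pvals


@dataclass
class DescriptiveSummary:
    categorical: pd.DataFrame  # variable, level, count, percent
    continuous: pd.DataFrame  # variable, median, q1, q3, formatted
    n: int

    def formatted(self, variable: str, level: str) -> str:
        row = self.categorical[
            (self.categorical["variable"] == variable)
            & (self.categorical["level"] == level)
        ].iloc[0]
        return f"{int(row['count'])} ({row['percent']:.1f})"


def descriptive_table(covariates: pd.DataFrame) -> DescriptiveSummary:
    """Cohort descriptives: counts with half-up one-decimal percentages for
    categorical covariates, "median (Q1, Q3)" for continuous ones."""
    if len(covariates) == 0:
        raise ValueError("empty cohort")
    n = len(covariates)
    cat_rows = []
    for var, freqs in table_marginals().items():
        if var not in covariates.columns:
            continue
        counts = covariates[var].value_counts()
        for level in freqs:
            c = int(counts.get(level, 0))
            cat_rows.append(
                {"variable": var, "level": level, "count": c,
                 "percent": _round_half_up(100.0 * c / n)}
            )
    cont_rows = []
    for var in continuous_marginals():
        if var not in covariates.columns:
            continue
        x = covariates[var].to_numpy(dtype=float)
        med, q1, q3 = np.median(x), np.quantile(x, 0.25), np.quantile(x, 0.75)
        cont_rows.append(
            {"variable": var, "median": med, "q1": q1, "q3": q3,
             "formatted": f"{med:g} ({q1:g}, {q3:g})"}
        )
    return DescriptiveSummary(
        categorical=pd.DataFrame(cat_rows),
        continuous=pd.DataFrame(cont_rows),
        n=n,
    )
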