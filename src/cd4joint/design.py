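"""Design-matrix construction and the visit-time schedule.

Covariate tables use tidy string-coded categoricals; model terms are named
dummy/continuous columns (reference coding fixed by the cohort tables:
male, urban, without-partner, tertiary education, high income, WHO stage IV,
cellphone owner, disclosed, good adherence are the omitted levels).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "TERM_BUILDERS",
    "build_design",
    "default_schedule",
    "coded_time",
    "standardize_time",
]

TERM_BUILDERS = {
    "intercept": lambda df: np.ones(len(df)),
    "age": lambda df: df["age"].to_numpy(float),
    "weight": lambda df: df["weight"].to_numpy(float),
    "baseline_cd4": lambda df: df["baseline_cd4"].to_numpy(float),
    "female": lambda df: (df["sex"] == "female").to_numpy(float),
    "rural": lambda df: (df["residence"] == "rural").to_numpy(float),
    "with_partner": lambda df: (df["marital"] == "with_partner").to_numpy(float),
    "educ_none": lambda df: (df["education"] == "none").to_numpy(float),
    "educ_primary": lambda df: (df["education"] == "primary").to_numpy(float),
    "educ_secondary": lambda df: (df["education"] == "secondary").to_numpy(float),
    "income_low": lambda df: (df["income"] == "low").to_numpy(float),
    "income_middle": lambda df: (df["income"] == "middle").to_numpy(float),
    "no_cellphone": lambda df: (df["cellphone"] == "no").to_numpy(float),
    "adherence_poor": lambda df: (df["adherence"] == "poor").to_numpy(float),
    "adherence_fair": lambda df: (df["adherence"] == "fair").to_numpy(float),
    "no_disclosure": lambda df: (df["disclosure"] == "no").to_numpy(float),
    "who_stage1": lambda df: (df["who_stage"] == "stage1").to_numpy(float),
    "who_stage2": lambda df: (df["who_stage"] == "stage2").to_numpy(float),
    "who_stage3": lambda df: (df["who_stage"] == "stage3").to_numpy(float),
}


def build_design(
    covariates: pd.DataFrame,
    terms: list[str],
    time_std: np.ndarray | None = None,
    row_patient: np.ndarray | None = None,
) -> np.ndarray:
    """Build an (n_rows, len(terms)) design matrix.

    ``terms`` may include ``"time"`` when ``time_std`` (the standardised
    visit time per output row) is given.  When ``row_patient`` is given, the
    patient-level covariate columns are expanded to one row per entry of
    ``row_patient`` (integer positions into ``covariates``).
    """
    cols = []
    for term in terms:
        if term == "time":
            if time_std is None:
                raise ValueError("'time' term requires a time_std vector")
            cols.append(np.asarray(time_std, dtype=float))
            continue
        try:
            col = TERM_BUILDERS[term](covariates)
        except KeyError as exc:
            raise ValueError(f"unknown design term {term!r}") from exc
        if row_patient is not None:
            col = col[np.asarray(row_patient)]
        cols.append(col)
    return np.column_stack(cols) if cols else np.empty((_nrows(covariates, row_patient, time_std), 0))


def _nrows(covariates, row_patient, time_std):
    if time_std is not None:
        return len(time_std)
    if row_patient is not None:
        return len(row_patient)
    return len(covariates)


def default_schedule(max_followups: int = 20) -> np.ndarray:
    """Visit times in months: monthly for six months, then quarterly.

    Visit j has time j months for j <= 6 and 6 + 3(j-6) months beyond, to a
    configurable administrative horizon (default 20 visits = 48 months, a
    four-year study window).
    """
    if max_followups < 1:
        raise ValueError("max_followups must be >= 1")
    j = np.arange(1, max_followups + 1)
    return np.where(j <= 6, j, 6 + 3 * (j - 6)).astype(float)


def coded_time(visit_index: np.ndarray, n_visits: int | None = None) -> np.ndarray:
    """Model time coding: visits since the first modelled change visit.

    The follow-up clock of both submodels is the visit number, so the
    longitudinal time covariate (and the random slope) is coded per
    follow-up visit: one unit is one additional visit, matching the
    per-follow-up interpretation of the fitted time coefficient.  The origin
    sits at the first on-treatment change visit (j = 2), so the random
    intercept is the patient's level at entry into the change series; an
    origin anchored mid-study would let a steep slope mimic a low early
    level for patients who default early, confounding the intercept and
    slope effects under informative dropout.
    """
    return np.asarray(visit_index, dtype=float) - 2.0


def standardize_time(months: np.ndarray, schedule: np.ndarray) -> np.ndarray:
    """Standardise visit times against the schedule's mean and SD."""
    schedule = np.asarray(schedule, dtype=float)
    mu = schedule.mean()
    sd = schedule.std()
    if sd == 0:
        return np.zeros_like(np.asarray(months, dtype=float))
    return (np.asarray(months, dtype=float) - mu) / sd
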