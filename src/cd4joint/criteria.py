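"""Fit-criteria container shared by the longitudinal and survival fits."""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["FitCriteria"]


@dataclass
class FitCriteria:
    """Information criteria and Pearson dispersion for one fitted model.

    ``pearson_chi2`` / ``dof`` may be None where the quantity is undefined
    for the estimation engine (e.g. a partial-likelihood Cox fit); such cells
    are reported as unavailable rather than fabricated.
    """

    loglik: float
    k: int
    nobs: int
    pearson_chi2: float | None = None
    dof: int | None = None
    note: str = ""

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.k * math.log(self.nobs)

    @property
    def pearson_ratio(self) -> float | None:
        if self.pearson_chi2 is None or not self.dof:
            return None
        return self.pearson_chi2 / self.dof

    def as_dict(self) -> dict:
        return {
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "pearson_chi2": self.pearson_chi2,
            "dof": self.dof,
            "pearson_ratio": self.pearson_ratio,
            "k": self.k,
            "nobs": self.nobs,
            "note": self.note,
        }
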