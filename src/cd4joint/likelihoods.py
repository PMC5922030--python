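"""Shared likelihood kernels.

The Poisson-log-normal marginal density has no closed form; it is evaluated
by Gauss-Hermite quadrature over the visit-level perturbation.  These kernels
are the building blocks of both the separate submodel fits and the joint
model, so the separability identity (joint = longitudinal + survival at zero
loadings) holds exactly.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "poisson_loglik",
    "pln_marginal_loglik",
    "weibull_loglik",
    "mvn2_loglik",
    "normal_loglik",
]

_ETA_CAP = 30.0  # overflow guard on the log-mean scale


def poisson_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    """Poisson log-likelihood with log mean ``eta`` (summed)."""
    eta = np.clip(eta, -_ETA_CAP, _ETA_CAP)
    return float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1.0)))


def pln_marginal_loglik(
    y: np.ndarray,
    eta: np.ndarray,
    var: np.ndarray | float,
    nodes: int = 25,
) -> float:
    """Poisson-log-normal log-likelihood, marginal over the visit perturbation.

    ``y | eps ~ Poisson(exp(eta + eps))`` with ``eps ~ N(0, var)``; ``var``
    may be scalar or per-observation.  Degenerate variances reduce to the
    plain Poisson likelihood.

    The quadrature is adaptive: each observation's integrand is re-centred
    at its mode with a curvature-matched width (plain Gauss-Hermite centred
    at zero misses the mass entirely once |log(y) - eta| is large relative
    to the perturbation SD).
    """
    y = np.asarray(y, dtype=float)
    eta = np.asarray(eta, dtype=float)
    var = np.broadcast_to(np.asarray(var, dtype=float), y.shape).copy()
    out = 0.0
    degen = var <= 1e-12
    if degen.any():
        out += poisson_loglik(y[degen], eta[degen])
    if (~degen).any():
        yy, ee, vv = y[~degen], eta[~degen], var[~degen]
        # mode of f(e) = y(eta+e) - exp(eta+e) - e^2/(2v) by damped Newton
        # (f is strictly concave)
        m = np.clip(np.log(yy + 0.5) - ee, -30.0, 30.0)
        for _ in range(30):
            lam = np.clip(ee + m, -_ETA_CAP, _ETA_CAP)
            g = yy - np.exp(lam) - m / vv
            h = np.exp(lam) + 1.0 / vv
            step = np.clip(g / h, -2.0, 2.0)
            m = m + step
            if np.max(np.abs(step)) < 1e-10:
                break
        lam = np.clip(ee + m, -_ETA_CAP, _ETA_CAP)
        h = np.exp(lam) + 1.0 / vv
        s = 1.0 / np.sqrt(h)
        x, w = np.polynomial.hermite.hermgauss(nodes)
        e_nodes = m[:, None] + np.sqrt(2.0) * s[:, None] * x[None, :]
        lam_n = np.clip(ee[:, None] + e_nodes, -_ETA_CAP, _ETA_CAP)
        # log integrand: Poisson mass x normal density of the perturbation
        logf = (
            yy[:, None] * lam_n
            - np.exp(lam_n)
            - gammaln(yy + 1.0)[:, None]
            - 0.5 * e_nodes**2 / vv[:, None]
            - 0.5 * np.log(2.0 * np.pi * vv)[:, None]
        )
        out += float(
            np.sum(
                logsumexp(np.log(w)[None, :] + x[None, :] ** 2 + logf, axis=1)
                + 0.5 * np.log(2.0) + np.log(s)
            )
        )
    return out


def weibull_loglik(
    t: np.ndarray,
    event: np.ndarray,
    eta: np.ndarray | float,
    rho: float,
    phi: float,
) -> float:
    """Censored Weibull proportional-hazards log-likelihood (summed).

    Hazard ``h(t) = phi * rho * t^(rho-1) * exp(eta)``; events contribute
    ``log h`` and everyone contributes ``-H(t)`` with cumulative hazard
    ``H(t) = phi * t^rho * exp(eta)``.
    """
    t = np.asarray(t, dtype=float)
    event = np.asarray(event, dtype=float)
    eta = np.broadcast_to(np.asarray(eta, dtype=float), t.shape)
    if rho <= 0 or phi <= 0:
        return -np.inf
    if np.any(t <= 0):
        raise ValueError("event/censoring times must be positive")
    eta = np.clip(eta, -_ETA_CAP, _ETA_CAP)
    logh = np.log(phi) + np.log(rho) + (rho - 1.0) * np.log(t) + eta
    H = phi * t**rho * np.exp(eta)
    return float(np.sum(event * logh - H))


def mvn2_loglik(nu0: np.ndarray, nu1: np.ndarray, Sigma: np.ndarray) -> float:
    """Sum of bivariate-normal(0, Sigma) log densities."""
    det = Sigma[0, 0] * Sigma[1, 1] - Sigma[0, 1] ** 2
    if det <= 0:
        return -np.inf
    P = np.array([[Sigma[1, 1], -Sigma[0, 1]], [-Sigma[0, 1], Sigma[0, 0]]]) / det
    quad = P[0, 0] * nu0**2 + 2 * P[0, 1] * nu0 * nu1 + P[1, 1] * nu1**2
    n = len(np.atleast_1d(nu0))
    return float(-0.5 * np.sum(quad) - n * np.log(2 * np.pi) - 0.5 * n * np.log(det))


def normal_loglik(x: np.ndarray, var: float) -> float:
    """Sum of N(0, var) log densities (0 for an empty or degenerate case)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if var <= 0:
        return 0.0 if np.allclose(x, 0) else -np.inf
    return float(-0.5 * np.sum(x**2) / var - 0.5 * len(x) * np.log(2 * np.pi * var))
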