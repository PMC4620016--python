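"""Independent oracles used by the test suite.

High-precision quadrature (mpmath) for the censored-marker integral and the
truncated tilted-normal moments, and a brute-force evaluation of the
observed-data log-likelihood that enumerates classes per patient.  These are
deliberately written against the model's defining integrals, not against the
closed forms used by the implementation.
"""

from __future__ import annotations

import math

import mpmath as mp
import numpy as np


def _log_integrand(u, y, m, sigma):
    return -(u - y) - (u - m) ** 2 / (2 * sigma**2) - mp.log(sigma * mp.sqrt(2 * mp.pi))


def _breakpoints(y, m, sigma):
    # integrand peaks at u* = max(y, m - sigma^2); scale there and split
    ustar = max(y, m - sigma**2)
    pts = sorted({y, ustar, ustar + sigma, ustar + 5 * sigma})
    return [p for p in pts if p >= y] + [mp.inf], ustar


def log_quad_censored_integral(y, m, sigma, dps: int = 30) -> mp.mpf:
    """log integral_y^inf e^{-(u-y)} Normal(u; m, sigma^2) du.

    The integrand is rescaled by its peak value before tanh-sinh quadrature
    so extreme tails (values ~ e^{-400}) keep full relative precision.
    """
    with mp.workdps(dps):
        y, m, sigma = mp.mpf(y), mp.mpf(m), mp.mpf(sigma)
        pts, ustar = _breakpoints(y, m, sigma)
        top = _log_integrand(ustar, y, m, sigma)
        val = mp.quad(lambda u: mp.e ** (_log_integrand(u, y, m, sigma) - top), pts)
        return top + mp.log(val)


def quad_censored_integral(y, m, sigma, dps: int = 30) -> mp.mpf:
    return mp.e ** log_quad_censored_integral(y, m, sigma, dps)


def quad_censored_moment(y, m, sigma, r: int, dps: int = 30) -> float:
    """E[z^r] under the density proportional to e^{-(z-y)} phi((z-m)/sigma) on [y, inf)."""
    with mp.workdps(dps):
        y, m, sigma = mp.mpf(y), mp.mpf(m), mp.mpf(sigma)
        pts, ustar = _breakpoints(y, m, sigma)
        top = _log_integrand(ustar, y, m, sigma)
        f = lambda u: mp.e ** (_log_integrand(u, y, m, sigma) - top)
        num = mp.quad(lambda u: u**r * f(u), pts)
        den = mp.quad(f, pts)
        return float(num / den)


def brute_force_loglik(data, params) -> float:
    """Observed log-likelihood by per-patient class enumeration + quadrature."""
    A = params.full_alpha()
    total = 0.0
    for i in range(data.n):
        eta = A @ data.V[i]
        pi = np.exp(eta - eta.max())
        pi = pi / pi.sum()
        like = 0.0
        for k in range(params.K):
            m = float(data.X_marker[i] @ params.betas[k])
            p_die = 1.0 / (1.0 + math.exp(-float(data.X_death[i] @ params.gammas[k])))
            if data.died[i]:
                marker = float(quad_censored_integral(float(data.y_obs[i]), m, params.sigma))
                like += pi[k] * marker * p_die
            else:
                z = (data.y_obs[i] - m) / params.sigma
                marker = math.exp(-0.5 * z * z) / (params.sigma * math.sqrt(2 * math.pi))
                like += pi[k] * marker * (1.0 - p_die)
        total += math.log(like)
    return total


def brute_force_posterior(record_idx: int, data, params) -> np.ndarray:
    """Posterior membership for one record via quadrature Bayes computation."""
    A = params.full_alpha()
    i = record_idx
    eta = A @ data.V[i]
    pi = np.exp(eta - eta.max())
    pi = pi / pi.sum()
    weights = np.empty(params.K)
    for k in range(params.K):
        m = float(data.X_marker[i] @ params.betas[k])
        p_die = 1.0 / (1.0 + math.exp(-float(data.X_death[i] @ params.gammas[k])))
        if data.died[i]:
            marker = float(quad_censored_integral(float(data.y_obs[i]), m, params.sigma))
            weights[k] = pi[k] * marker * p_die
        else:
            z = (data.y_obs[i] - m) / params.sigma
            marker = math.exp(-0.5 * z * z) / (params.sigma * math.sqrt(2 * math.pi))
            weights[k] = pi[k] * marker * (1.0 - p_die)
    return weights / weights.sum()
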