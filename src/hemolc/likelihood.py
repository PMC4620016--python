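"""Probability components of the joint marker/survival mixture likelihood.

Every patient contributes a K-term mixture: membership probability times a
marker term times a mortality term.  For survivors the marker term is the
Gaussian density of the observed log units; for patients who died within
24 h it is the induced-censoring integral

    integral_{y}^{inf} e^{-(u - y)} (1/sigma) phi((u - m)/sigma) du
        = exp(y - m + sigma^2/2) * Phi((m - sigma^2 - y)/sigma),

the likelihood of observing log amount ``y`` when the observed amount is
uniform on [0, exp(true amount)].  Everything is assembled in log space with
log-sum-exp; the normal CDF enters through its log for extreme arguments.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, log_expit, logsumexp
from scipy.stats import norm

from .data import ModelParameters, TraumaData, as_data

__all__ = [
    "membership_probabilities",
    "log_membership",
    "mortality_probability",
    "censored_marker_integral",
    "log_censored_marker_integral",
    "censored_marker_moments",
    "component_loglik",
    "observed_loglik",
]


def log_membership(V, params: ModelParameters) -> np.ndarray:
    """Log class-membership probabilities, one row per patient.

    Accepts a single covariate vector or an (n, d_v) design matrix; returns
    the matching (K,) vector or (n, K) matrix of log probabilities under the
    multinomial-logit model with class K as reference.
    """
    V = np.asarray(V, dtype=float)
    single = V.ndim == 1
    V2 = V[None, :] if single else V
    A = params.full_alpha()  # (K, d_v)
    if V2.shape[1] != A.shape[1]:
        raise ValueError(
            f"membership covariate length {V2.shape[1]} does not match "
            f"alpha dimension {A.shape[1]}"
        )
    eta = V2 @ A.T  # (n, K)
    logpi = eta - logsumexp(eta, axis=1, keepdims=True)
    return logpi[0] if single else logpi


def membership_probabilities(v, params: ModelParameters) -> np.ndarray:
    """Class-membership probabilities pi_k(v); rows sum to one."""
    return np.exp(log_membership(v, params))


def mortality_probability(x, gamma_k) -> np.ndarray:
    """P(death within 24 h | class k, x) under the class-k logistic model."""
    x = np.asarray(x, dtype=float)
    gamma_k = np.asarray(gamma_k, dtype=float)
    if x.shape[-1] != gamma_k.shape[0]:
        raise ValueError(
            f"covariate length {x.shape[-1]} does not match gamma length "
            f"{gamma_k.shape[0]}"
        )
    return expit(x @ gamma_k)


def log_censored_marker_integral(y_obs, m, sigma) -> np.ndarray:
    """Log of the death-censored marker likelihood term (closed form).

    Broadcasts over ``y_obs`` and ``m``.  The integrand is the exponential
    tilt e^{-(u-y)} of the normalized Normal(m, sigma^2) density on
    [y, infinity); the closed form is evaluated through the normal log-CDF so
    that deep truncation (m far below y, or tiny sigma) underflows gracefully
    instead of returning -inf prematurely.
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    y = np.asarray(y_obs, dtype=float)
    m = np.asarray(m, dtype=float)
    return (y - m + 0.5 * sigma**2) + norm.logcdf((m - sigma**2 - y) / sigma)


def censored_marker_integral(y_obs, m, sigma) -> np.ndarray:
    return np.exp(log_censored_marker_integral(y_obs, m, sigma))


def censored_marker_moments(y_obs, m, sigma):
    """First and second conditional moments of the uncensored log marker.

    For a censored record the uncensored value z has density proportional to
    e^{-(z - y)} phi((z - m)/sigma) on [y, infinity), which is exactly a
    Normal(m - sigma^2, sigma^2) truncated below at y.  Moments come from
    truncated-normal formulas with the inverse Mills ratio computed as
    exp(logpdf - logsf), which stays accurate arbitrarily deep into the tail.

    Returns ``(e_z, e_z2)`` broadcast over the inputs, with ``e_z >= y_obs``
    and ``e_z2 >= e_z**2``.
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    y = np.asarray(y_obs, dtype=float)
    m = np.asarray(m, dtype=float)
    mu = m - sigma**2  # mean of the tilted (pre-truncation) normal
    a = (y - mu) / sigma
    lam = np.exp(norm.logpdf(a) - norm.logsf(a))  # inverse Mills ratio
    e_z = mu + sigma * lam
    var = sigma**2 * np.clip(1.0 + a * lam - lam**2, 0.0, None)
    e_z = np.maximum(e_z, y)  # guard tiny negative round-off at deep truncation
    return e_z, var + e_z**2


def component_loglik(data, params: ModelParameters) -> np.ndarray:
    """(n, K) matrix of per-patient, per-class joint log-likelihood terms.

    Entry (i, k) is log pi_ik + log f(y_i | k) + log P(w_i | k), with the
    censored marker branch used when the patient died.
    """
    d = as_data(data)
    if d.d_xm != params.betas.shape[1]:
        raise ValueError(
            f"marker covariate dimension {d.d_xm} does not match beta "
            f"dimension {params.betas.shape[1]}"
        )
    if d.d_xd != params.gammas.shape[1]:
        raise ValueError(
            f"death covariate dimension {d.d_xd} does not match gamma "
            f"dimension {params.gammas.shape[1]}"
        )
    M = d.X_marker @ params.betas.T  # (n, K) marker means
    eta_w = d.X_death @ params.gammas.T  # (n, K) death logits
    logpi = log_membership(d.V, params)
    y = d.y_obs[:, None]
    died = d.died[:, None].astype(bool)

    marker = np.where(
        died,
        log_censored_marker_integral(y, M, params.sigma),
        norm.logpdf(y, loc=M, scale=params.sigma),
    )
    death = np.where(died, log_expit(eta_w), log_expit(-eta_w))
    return logpi + marker + death


def observed_loglik(data, params: ModelParameters) -> float:
    """Observed-data log-likelihood of the K-class joint mixture."""
    comp = component_loglik(data, params)
    ll = logsumexp(comp, axis=1)
    if not np.all(np.isfinite(ll)):
        bad = np.flatnonzero(~np.isfinite(ll))
        raise FloatingPointError(
            f"non-finite likelihood contribution for record(s) at index {bad[:5]}"
        )
    return float(ll.sum())
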