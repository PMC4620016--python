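"""Standard errors from the empirical observed information matrix.

Per-patient scores are the conditional expectations, given the observed data,
of the complete-data score — by Fisher's identity these equal the observed-data
scores, so their outer-product sum is the empirical observed information.  The
residual SD is parameterized as log(sigma) throughout this module.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .data import ModelParameters, as_data
from .em import e_step
from .likelihood import log_membership

__all__ = [
    "InferenceResult",
    "individual_scores",
    "empirical_information",
    "compute_inference",
    "wald_tests",
]


@dataclasses.dataclass(frozen=True)
class InferenceResult:
    """Point estimates with empirical-information covariance and Wald tests.

    ``estimates`` flattens the parameters in the order alpha rows, beta rows,
    gamma rows, log(sigma); ``names`` labels each entry.
    """

    estimates: np.ndarray
    names: list
    cov: np.ndarray
    se: np.ndarray
    wald_z: np.ndarray
    p_values: np.ndarray
    singular: bool = False

    @property
    def sigma_se(self) -> float:
        """Delta-method SE of sigma itself (sigma * se of log sigma)."""
        import math

        return math.exp(self.estimates[-1]) * self.se[-1]


def individual_scores(data, params: ModelParameters) -> np.ndarray:
    """(n, P) matrix of per-patient observed-data score vectors.

    Assembled from the posterior memberships and censored-marker moments:
    the expected complete-data score for the membership block is
    v (g~_k - pi_k); for beta_k it is g~_k x (ytilde_k - x'beta_k)/sigma^2;
    for gamma_k it is g~_k x (w - p_k); and for log(sigma) it is
    -1 + sigma^-2 sum_k g~_k E[(z - x'beta_k)^2].
    """
    d = as_data(data)
    K = params.K
    state = e_step(d, params)
    G = state.g
    pi = np.exp(log_membership(d.V, params))
    w = d.died.astype(bool)
    sigma2 = params.sigma**2

    M = d.X_marker @ params.betas.T
    ytilde = np.where(w[:, None], state.z_mean, d.y_obs[:, None])
    sq = np.where(
        w[:, None],
        state.z_sq - 2.0 * state.z_mean * M + M**2,
        (d.y_obs[:, None] - M) ** 2,
    )
    p_death = expit(d.X_death @ params.gammas.T)

    blocks = []
    for k in range(K - 1):
        blocks.append(d.V * (G[:, k] - pi[:, k])[:, None])
    for k in range(K):
        blocks.append(d.X_marker * (G[:, k] * (ytilde[:, k] - M[:, k]) / sigma2)[:, None])
    for k in range(K):
        blocks.append(d.X_death * (G[:, k] * (d.died - p_death[:, k]))[:, None])
    blocks.append((-1.0 + (G * sq).sum(axis=1) / sigma2)[:, None])
    return np.hstack(blocks)


def empirical_information(data, params: ModelParameters) -> np.ndarray:
    """Sum of outer products of individual scores (symmetric PSD)."""
    S = individual_scores(data, params)
    return S.T @ S


def compute_inference(data, params: ModelParameters) -> InferenceResult:
    """Covariance, SEs and Wald tests at (or near) the MLE.

    The covariance estimate is the inverse empirical information; a
    pseudo-inverse is substituted, with a warning and a ``singular`` flag,
    when the information matrix is numerically singular.
    """
    info = empirical_information(data, params)
    singular = False
    cond = np.linalg.cond(info)
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn(
            "empirical information matrix is numerically singular; "
            "using a pseudo-inverse",
            RuntimeWarning,
        )
        cov = np.linalg.pinv(info)
        singular = True
    else:
        cov = np.linalg.inv(info)
    cov = 0.5 * (cov + cov.T)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    est = params.flatten(log_sigma=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, est / np.where(se > 0, se, 1.0), np.nan)
    p = np.where(np.isfinite(z), 2.0 * norm.sf(np.abs(z)), np.nan)
    return InferenceResult(
        estimates=est,
        names=params.param_names(),
        cov=cov,
        se=se,
        wald_z=z,
        p_values=p,
        singular=singular,
    )


def wald_tests(result: InferenceResult) -> pd.DataFrame:
    """Wald z statistics and two-sided normal p-values, one row per parameter."""
    return pd.DataFrame(
        {
            "parameter": result.names,
            "estimate": result.estimates,
            "se": result.se,
            "z": result.wald_z,
            "p_value": result.p_values,
        }
    )
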