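"""EM estimation of the joint latent-class model.

The E-step computes posterior class memberships and, for death-censored
records, the conditional moments of the uncensored log marker (a truncated
tilted normal).  The M-step solves a fractional-response multinomial logistic
model for the membership coefficients, class-wise weighted least squares for
the marker coefficients, class-wise weighted logistic regressions for the
mortality coefficients, and a closed-form update for the shared variance.
A multi-start driver guards against local maxima; BIC compares class counts.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit, logsumexp

from .data import LatentState, ModelParameters, TraumaData, as_data
from .likelihood import censored_marker_moments, component_loglik, observed_loglik

__all__ = [
    "EMConfig",
    "FitResult",
    "posterior_membership",
    "e_step",
    "m_step",
    "fit_em",
    "bic_scan",
]

logger = logging.getLogger("hemolc")

#: coefficient magnitude beyond which a logistic fit is treated as separated
_COEF_BOUND = 30.0


@dataclasses.dataclass(frozen=True)
class EMConfig:
    """Settings for the multi-start EM driver.

    ``n_starts`` random initializations (20 mirrors the multi-start protocol
    used for single-dataset analyses); convergence when the relative
    log-likelihood change drops below ``tol``.  ``ridge`` is the fallback
    penalty applied to logistic subproblems that show quasi-separation.
    """

    n_starts: int = 20
    max_iter: int = 2000
    tol: float = 1e-8
    seed: int = 0
    ridge: float = 1e-4

    def __post_init__(self):
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.ridge < 0:
            raise ValueError("ridge must be nonnegative")


@dataclasses.dataclass(frozen=True)
class FitResult:
    """Converged EM fit: parameters, trace and model-selection quantities."""

    params: ModelParameters
    loglik: float
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    start_index: int
    n_params: int
    n_obs: int
    bic: float
    ridge_flagged: bool = False

    def __post_init__(self):
        object.__setattr__(
            self, "loglik_trace", np.asarray(self.loglik_trace, dtype=float)
        )


def posterior_membership(data, params: ModelParameters) -> np.ndarray:
    """Posterior class probabilities given marker, survival and covariates.

    Bayes' rule over the K mixture components; proportional to the prior
    membership probability times the class-conditional marker and mortality
    likelihood terms.  Returns an (n, K) row-stochastic matrix (a (K,)
    vector for a single record).
    """
    d = as_data(data)
    comp = component_loglik(d, params)
    norm_ = logsumexp(comp, axis=1, keepdims=True)
    if not np.all(np.isfinite(norm_)):
        bad = np.flatnonzero(~np.isfinite(norm_.ravel()))
        ids = d.ids[bad[:5]]
        raise FloatingPointError(
            f"zero total likelihood (all classes underflow) for record(s) {ids}"
        )
    g = np.exp(comp - norm_)
    return g[0] if not isinstance(data, TraumaData) and d.n == 1 else g


def e_step(data, params: ModelParameters) -> LatentState:
    """Posterior memberships plus censored-marker conditional moments."""
    d = as_data(data)
    g = posterior_membership(d, params)
    g = np.atleast_2d(g)
    K = params.K
    z_mean = np.full((d.n, K), np.nan)
    z_sq = np.full((d.n, K), np.nan)
    cens = d.died.astype(bool)
    if cens.any():
        M = d.X_marker[cens] @ params.betas.T
        ez, ez2 = censored_marker_moments(d.y_obs[cens][:, None], M, params.sigma)
        z_mean[cens] = ez
        z_sq[cens] = ez2
    return LatentState(g=g, z_mean=z_mean, z_sq=z_sq)


# --------------------------------------------------------------------------
# M-step building blocks


def _multinomial_obj(V, G, A_free, ridge):
    """Penalized fractional-response multinomial log-likelihood and gradient."""
    K = G.shape[1]
    A = np.vstack([A_free, np.zeros((1, V.shape[1]))])
    eta = V @ A.T
    lse = logsumexp(eta, axis=1)
    ll = float((G * eta).sum() - lse.sum()) - 0.5 * ridge * float((A_free**2).sum())
    pi = np.exp(eta - lse[:, None])
    grad = (G - pi)[:, : K - 1].T[:, :, None] * V[None, :, :]
    grad = grad.sum(axis=1) - ridge * A_free  # (K-1, d_v)
    return ll, grad.ravel(), pi


def _fit_fractional_multinomial(V, G, start=None, ridge=0.0, max_iter=200, tol=1e-10):
    """Newton maximization of the G-weighted multinomial-logit likelihood.

    ``G`` holds fractional responses (posterior memberships) summing to one
    per row.  Returns the (K-1, d_v) free coefficient block.
    """
    n, d_v = V.shape
    K = G.shape[1]
    if K == 1:
        return np.zeros((0, d_v))
    A = np.zeros((K - 1, d_v)) if start is None else np.array(start, dtype=float)
    ll, grad, pi = _multinomial_obj(V, G, A, ridge)
    for _ in range(max_iter):
        # Hessian of the multinomial log-likelihood, block (j, l)
        H = np.zeros(((K - 1) * d_v, (K - 1) * d_v))
        for j in range(K - 1):
            for l in range(j, K - 1):
                wjl = pi[:, j] * ((j == l) - pi[:, l])
                block = (V * wjl[:, None]).T @ V
                H[j * d_v : (j + 1) * d_v, l * d_v : (l + 1) * d_v] = block
                H[l * d_v : (l + 1) * d_v, j * d_v : (j + 1) * d_v] = block.T
        H += ridge * np.eye((K - 1) * d_v)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "singular Hessian in membership logistic subproblem"
            )
        t = 1.0
        for _ in range(40):
            A_new = A + t * step.reshape(K - 1, d_v)
            ll_new, grad_new, pi_new = _multinomial_obj(V, G, A_new, ridge)
            if ll_new >= ll - 1e-12:
                break
            t /= 2
        A, ll_prev, ll, grad, pi = A_new, ll, ll_new, grad_new, pi_new
        if np.max(np.abs(grad)) < tol * (1 + abs(ll)) and ll - ll_prev < tol * (
            1 + abs(ll)
        ):
            break
    return A


def _logistic_obj(X, y, wts, b, ridge):
    eta = X @ b
    p = expit(eta)
    # weighted Bernoulli log-likelihood, stable via log_expit
    ll = float(np.sum(wts * (y * log_expit(eta) + (1 - y) * log_expit(-eta))))
    ll -= 0.5 * ridge * float(b @ b)
    grad = X.T @ (wts * (y - p)) - ridge * b
    return ll, grad, p


def _fit_weighted_logistic(
    X, y, wts, start=None, ridge=0.0, max_iter=100, tol=1e-10
):
    """Newton/IRLS for a weighted (possibly fractional-weight) logistic fit."""
    b = np.zeros(X.shape[1]) if start is None else np.array(start, dtype=float)
    ll, grad, p = _logistic_obj(X, y, wts, b, ridge)
    for _ in range(max_iter):
        w_irls = wts * p * (1 - p)
        H = (X * w_irls[:, None]).T @ X + ridge * np.eye(X.shape[1])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError("singular Hessian in logistic subproblem")
        t = 1.0
        for _ in range(40):
            b_new = b + t * step
            ll_new, grad_new, p_new = _logistic_obj(X, y, wts, b_new, ridge)
            if ll_new >= ll - 1e-12:
                break
            t /= 2
        b, ll_prev, ll, grad, p = b_new, ll, ll_new, grad_new, p_new
        if np.max(np.abs(grad)) < tol * (1 + abs(ll)) and ll - ll_prev < tol * (
            1 + abs(ll)
        ):
            break
    return b


def _logistic_with_fallback(fit_fn, ridge):
    """Run a logistic subproblem; refit with a ridge penalty on separation."""
    try:
        coef = fit_fn(0.0)
    except np.linalg.LinAlgError:
        return fit_fn(ridge), True
    if coef.size and np.max(np.abs(coef)) > _COEF_BOUND:
        return fit_fn(ridge), True
    return coef, False


def m_step(
    data, state: LatentState, current: ModelParameters, ridge: float = 1e-4
) -> tuple[ModelParameters, bool]:
    """One M-step: maximize the expected complete-data log-likelihood.

    Returns the updated parameters and a flag saying whether any logistic
    subproblem needed the ridge fallback (quasi-separation).
    """
    d = as_data(data)
    G = state.g
    K = G.shape[1]
    w = d.died.astype(bool)

    # working marker response: observed value for survivors, conditional mean
    # of the uncensored value for the dead
    ytilde = np.where(w[:, None], state.z_mean, d.y_obs[:, None])

    # membership coefficients
    flagged = False
    alpha, f = _logistic_with_fallback(
        lambda r: _fit_fractional_multinomial(d.V, G, start=current.alpha, ridge=r),
        ridge,
    )
    flagged |= f

    # class-specific marker coefficients by weighted least squares
    betas = np.empty((K, d.d_xm))
    X = d.X_marker
    for k in range(K):
        Wk = G[:, k]
        XtW = X.T * Wk
        A = XtW @ X
        try:
            betas[k] = np.linalg.solve(A, XtW @ ytilde[:, k])
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                f"singular weighted marker design for class {k + 1}"
            )

    # class-specific mortality coefficients
    gammas = np.empty((K, d.d_xd))
    for k in range(K):
        coef, f = _logistic_with_fallback(
            lambda r, k=k: _fit_weighted_logistic(
                d.X_death, d.died.astype(float), G[:, k],
                start=current.gammas[k], ridge=r,
            ),
            ridge,
        )
        gammas[k] = coef
        flagged |= f

    # shared variance, closed form; censored records contribute
    # E[(z - x'beta)^2] = E[z^2] - 2 E[z] x'beta + (x'beta)^2
    M = X @ betas.T
    sq = np.where(
        w[:, None],
        state.z_sq - 2.0 * state.z_mean * M + M**2,
        (d.y_obs[:, None] - M) ** 2,
    )
    sigma2 = float((G * sq).sum() / d.n)
    sigma = math.sqrt(max(sigma2, 1e-24))

    return (
        ModelParameters(alpha=alpha, betas=betas, gammas=gammas, sigma=sigma),
        flagged,
    )


# --------------------------------------------------------------------------
# Multi-start driver


def _initial_params(data: TraumaData, K: int, rng: np.random.Generator) -> ModelParameters:
    """Data-informed random start.

    Soft class labels are drawn from a symmetric Dirichlet, a one-class model
    is fitted per component on those labels (treating all markers as exact),
    and the coefficients are jittered with N(0, 0.25) noise.
    """
    n = data.n
    G0 = rng.dirichlet(np.ones(K), size=n)
    y = data.y_obs
    state0 = LatentState(
        g=G0,
        z_mean=np.repeat(y[:, None], K, axis=1),
        z_sq=np.repeat(y[:, None] ** 2, K, axis=1),
    )
    dummy = ModelParameters(
        alpha=np.zeros((K - 1, data.d_v)),
        betas=np.zeros((K, data.d_xm)),
        gammas=np.zeros((K, data.d_xd)),
        sigma=1.0,
    )
    params, _ = m_step(data, state0, dummy)
    jitter = 0.5  # SD of the N(0, 0.25) coefficient noise
    alpha = params.alpha + rng.normal(0.0, jitter, size=params.alpha.shape)
    betas = params.betas + rng.normal(0.0, jitter, size=params.betas.shape)
    gammas = params.gammas + rng.normal(0.0, jitter, size=params.gammas.shape)
    return ModelParameters(alpha=alpha, betas=betas, gammas=gammas, sigma=params.sigma)


def _run_single_chain(data, K, config, rng, start_index):
    params = _initial_params(data, K, rng)
    ll = observed_loglik(data, params)
    trace = [ll]
    converged = False
    flagged = False
    for it in range(1, config.max_iter + 1):
        state = e_step(data, params)
        params, f = m_step(data, state, params, ridge=config.ridge)
        flagged |= f
        ll_new = observed_loglik(data, params)
        trace.append(ll_new)
        if ll_new < ll - 1e-6:
            logger.warning(
                "EM log-likelihood decreased by %.3g at iteration %d (start %d)",
                ll - ll_new, it, start_index,
            )
        if abs(ll_new - ll) / (abs(ll_new) + 1.0) < config.tol:
            converged = True
            ll = ll_new
            break
        ll = ll_new
    logger.info(
        "start %d: loglik=%.6f after %d iterations (converged=%s)",
        start_index, ll, len(trace) - 1, converged,
    )
    return params, np.array(trace), converged, flagged


def fit_em(data, K: int, config: EMConfig | None = None) -> FitResult:
    """Maximum-likelihood fit of the K-class joint model by multi-start EM.

    Runs ``config.n_starts`` independent EM chains from randomized,
    data-informed initializations and keeps the chain with the highest
    observed-data log-likelihood (ties broken toward the lowest start index).
    Classes in the returned parameters are ordered by descending marker
    intercept, so class 1 is the severe-hemorrhage-like class.  Deterministic
    given ``config.seed``.
    """
    if K < 1:
        raise ValueError(f"number of classes must be >= 1, got {K}")
    config = config or EMConfig()
    d = as_data(data)
    n_params = (K - 1) * d.d_v + K * (d.d_xm + d.d_xd) + 1
    if d.n <= n_params:
        raise ValueError(
            f"n={d.n} must exceed the number of parameters ({n_params}) "
            f"for a K={K} fit"
        )
    children = np.random.SeedSequence(config.seed).spawn(config.n_starts)
    best = None
    errors = []
    for s, child in enumerate(children):
        rng = np.random.default_rng(child)
        try:
            params, trace, converged, flagged = _run_single_chain(
                d, K, config, rng, s
            )
        except (np.linalg.LinAlgError, FloatingPointError, ValueError) as exc:
            errors.append(f"start {s}: {type(exc).__name__}: {exc}")
            continue
        ll = trace[-1]
        if best is None or ll > best[0] + 1e-10:
            best = (ll, s, params, trace, converged, flagged)
    if best is None:
        raise RuntimeError(
            "all EM starts failed:\n" + "\n".join(errors)
        )
    ll, s, params, trace, converged, flagged = best
    params, _ = params.canonical()
    return FitResult(
        params=params,
        loglik=float(ll),
        loglik_trace=trace,
        converged=converged,
        n_iter=len(trace) - 1,
        start_index=s,
        n_params=n_params,
        n_obs=d.n,
        bic=float(-2.0 * ll + n_params * math.log(d.n)),
        ridge_flagged=flagged,
    )


def bic_scan(data, K_range, config: EMConfig | None = None) -> pd.DataFrame:
    """Fit the model over a range of class counts and compare by BIC.

    Returns one row per K with the parameter count, maximized log-likelihood
    and BIC = -2 loglik + n_params log(n); the argmin-BIC row is flagged.
    The parameter count is (K-1) d_v + K (d_xm + d_xd) + 1.
    """
    config = config or EMConfig()
    d = as_data(data)
    rows = []
    for K in sorted(set(int(k) for k in K_range)):
        fit = fit_em(d, K, config)
        rows.append(
            {
                "K": K,
                "n_params": fit.n_params,
                "loglik": fit.loglik,
                "bic": fit.bic,
                "converged": fit.converged,
            }
        )
    table = pd.DataFrame(rows)
    table["best"] = table["bic"] == table["bic"].min()
    return table
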