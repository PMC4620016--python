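"""Synthetic data generation under the joint latent-class design.

The default scenario reproduces the two-class benchmark design: one
standard-normal membership covariate v with alpha = (0.5, 1), so roughly
60 % of patients fall in class 1; one Bernoulli(0.5) class-specific covariate
x; marker coefficients beta(1) = (log 15, -1, 1) and beta(2) = (log 5, 1, -1)
on (1, v, x); mortality coefficients gamma(1) = (1, -1), gamma(2) = (-1, 1)
on (1, x), giving marginal class mortalities of 62 % and 38 %.  Patients who
die have their marker censored multiplicatively: the observed amount is
uniform on [0, true amount] on the unit scale, i.e. log U is added on the
log scale.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.integrate import quad
from scipy.special import expit
from scipy.stats import norm

from .data import ModelParameters, TraumaData

__all__ = [
    "SimScenario",
    "simulate_dataset",
    "marginal_class1_probability",
    "marginal_mortality",
]

_LOG15 = math.log(15.0)
_LOG5 = math.log(5.0)


@dataclasses.dataclass(frozen=True)
class SimScenario:
    """Generative constants for one simulation setting.

    Defaults are the two-class benchmark design described in the module
    docstring; every field can be overridden, including to K > 2 by supplying
    more beta/gamma rows (alpha then needs K - 1 rows).
    """

    n: int
    sigma: float = 0.5
    alpha: tuple = ((0.5, 1.0),)
    betas: tuple = ((_LOG15, -1.0, 1.0), (_LOG5, 1.0, -1.0))
    gammas: tuple = ((1.0, -1.0), (-1.0, 1.0))
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        K = len(self.betas)
        if len(self.gammas) != K or len(self.alpha) != K - 1:
            raise ValueError(
                f"inconsistent class counts: {len(self.alpha)} alpha rows, "
                f"{len(self.betas)} beta rows, {len(self.gammas)} gamma rows"
            )
        if any(len(b) != 3 for b in self.betas):
            raise ValueError("each beta row must be (intercept, v, x) coefficients")
        if any(len(g) != 2 for g in self.gammas):
            raise ValueError("each gamma row must be (intercept, x) coefficients")
        if any(len(a) != 2 for a in self.alpha):
            raise ValueError("each alpha row must be (intercept, v) coefficients")

    @property
    def K(self) -> int:
        return len(self.betas)

    def true_parameters(self) -> ModelParameters:
        return ModelParameters(
            alpha=np.asarray(self.alpha, dtype=float),
            betas=np.asarray(self.betas, dtype=float),
            gammas=np.asarray(self.gammas, dtype=float),
            sigma=self.sigma,
        )


def simulate_dataset(scenario: SimScenario) -> tuple[TraumaData, np.ndarray]:
    """Draw a dataset plus ground-truth class labels (1-based).

    Each patient uses an independent substream of the scenario seed with a
    fixed draw order (v, x, class, w, epsilon, U), so growing ``n`` extends a
    dataset without reshuffling earlier patients.  For the dead, the log
    marker is the true value plus log U (observed amount uniform below the
    true amount); survivors are observed exactly.
    """
    K = scenario.K
    A = np.vstack([np.asarray(scenario.alpha, float), np.zeros(2)]) if K > 1 else np.zeros((1, 2))
    betas = np.asarray(scenario.betas, dtype=float)
    gammas = np.asarray(scenario.gammas, dtype=float)
    n = scenario.n

    v = np.empty(n)
    x = np.empty(n)
    w = np.empty(n, dtype=int)
    y_obs = np.empty(n)
    labels = np.empty(n, dtype=int)

    children = np.random.SeedSequence(scenario.seed).spawn(n)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        vi = rng.standard_normal()
        xi = 1.0 if rng.random() < 0.5 else 0.0
        eta = A @ np.array([1.0, vi])
        pi = np.exp(eta - eta.max())
        pi /= pi.sum()
        k = int(np.searchsorted(np.cumsum(pi), rng.random(), side="right"))
        k = min(k, K - 1)
        p_die = expit(gammas[k, 0] + gammas[k, 1] * xi)
        wi = 1 if rng.random() < p_die else 0
        eps = scenario.sigma * rng.standard_normal()
        u = rng.random()
        delta = math.log(u) if wi == 1 else 0.0
        y_true = betas[k, 0] + betas[k, 1] * vi + betas[k, 2] * xi + eps
        v[i], x[i], w[i], labels[i] = vi, xi, wi, k + 1
        y_obs[i] = y_true + delta

    data = TraumaData(
        y_obs=y_obs,
        died=w,
        V=np.column_stack([np.ones(n), v]),
        X_marker=np.column_stack([np.ones(n), v, x]),
        X_death=np.column_stack([np.ones(n), x]),
        ids=np.arange(n),
        rbc_units=np.exp(y_obs),
    )
    return data, labels


def marginal_class1_probability(alpha) -> float:
    """Marginal P(class 1) with a standard-normal membership covariate.

    Integrates logistic(alpha0 + alpha1 v) against the N(0, 1) density by
    adaptive quadrature (absolute accuracy ~1e-10).
    """
    alpha = np.asarray(alpha, dtype=float).ravel()
    if alpha.shape != (2,):
        raise ValueError(f"alpha must have two components, got {alpha.shape}")
    a0, a1 = alpha
    val, _ = quad(
        lambda t: expit(a0 + a1 * t) * norm.pdf(t),
        -np.inf,
        np.inf,
        epsabs=1e-12,
        epsrel=1e-10,
    )
    return float(val)


def marginal_mortality(gamma) -> float:
    """Marginal class mortality with a Bernoulli(0.5) covariate:
    0.5 logistic(gamma0) + 0.5 logistic(gamma0 + gamma1)."""
    gamma = np.asarray(gamma, dtype=float).ravel()
    if gamma.shape != (2,):
        raise ValueError(f"gamma must have two components, got {gamma.shape}")
    return float(0.5 * expit(gamma[0]) + 0.5 * expit(gamma[0] + gamma[1]))
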