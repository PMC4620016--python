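"""Patient-level data containers and joint latent-class model parameters.

The model couples three submodels through a latent class label ``k``:

* a multinomial-logit class-membership model on covariates ``v`` (leading 1),
* a class-specific Gaussian linear model for the log cumulative RBC units
  observed by min(24 h, death), on covariates ``x_marker``,
* a class-specific logistic model for death within 24 h, on ``x_death``.

Death censors the marker: when ``died == 1`` the observed amount is assumed
uniform on [0, true amount] on the original (unit) scale, i.e. the log marker
is shifted by ``log U`` with ``U ~ Uniform(0, 1)``.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

__all__ = [
    "PatientRecord",
    "TraumaData",
    "ModelParameters",
    "LatentState",
]


def _as_1d(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclasses.dataclass(frozen=True)
class PatientRecord:
    """A single subject's observed marker, survival status and covariates.

    ``y_obs`` is the natural log of the cumulative RBC units transfused by
    min(24 h, death); ``w = 1`` means death within 24 h, in which case the
    marker is censored below its uncensored value.  ``v`` and ``x`` carry a
    leading intercept 1.  ``x_death`` defaults to ``x`` (shared class-specific
    covariates for the marker and mortality submodels).
    """

    id: object
    y_obs: float
    w: int
    v: np.ndarray
    x: np.ndarray
    x_death: np.ndarray | None = None
    rbc_units: float | None = None

    def __post_init__(self):
        if self.w not in (0, 1):
            raise ValueError(f"survival indicator w must be 0 or 1, got {self.w!r}")
        object.__setattr__(self, "v", _as_1d(self.v, "v"))
        object.__setattr__(self, "x", _as_1d(self.x, "x"))
        if self.x_death is not None:
            object.__setattr__(self, "x_death", _as_1d(self.x_death, "x_death"))
        if not math.isfinite(self.y_obs):
            raise ValueError(f"y_obs must be finite, got {self.y_obs!r}")
        if self.rbc_units is not None:
            if self.rbc_units <= 0:
                raise ValueError("rbc_units must be positive")
            if abs(math.log(self.rbc_units) - self.y_obs) > 1e-9:
                raise ValueError("y_obs must equal log(rbc_units) exactly")

    @classmethod
    def from_units(
        cls,
        id: object,
        rbc_units: float,
        died: int,
        v: Sequence[float],
        x: Sequence[float],
        x_death: Sequence[float] | None = None,
    ) -> "PatientRecord":
        """Build a record from raw units, enforcing the >=1-unit inclusion rule."""
        if rbc_units < 1.0:
            raise ValueError(
                f"rbc_units must be >= 1 (study inclusion criterion), got {rbc_units}"
            )
        return cls(
            id=id,
            y_obs=math.log(rbc_units),
            w=int(died),
            v=np.asarray(v, dtype=float),
            x=np.asarray(x, dtype=float),
            x_death=None if x_death is None else np.asarray(x_death, dtype=float),
            rbc_units=float(rbc_units),
        )


@dataclasses.dataclass(frozen=True)
class TraumaData:
    """Vectorised sample of patients.

    Attributes
    ----------
    y_obs : (n,) float array of log cumulative RBC units by min(24 h, death).
    died : (n,) int array, 1 = death within 24 h (marker censored).
    V : (n, d_v) membership design matrix with leading intercept column.
    X_marker : (n, d_xm) marker design matrix with leading intercept column.
    X_death : (n, d_xd) mortality design matrix with leading intercept column.
    ids : (n,) patient identifiers.
    rbc_units : optional (n,) array of observed units (exp of ``y_obs``).
    """

    y_obs: np.ndarray
    died: np.ndarray
    V: np.ndarray
    X_marker: np.ndarray
    X_death: np.ndarray
    ids: np.ndarray
    rbc_units: np.ndarray | None = None

    def __post_init__(self):
        y = np.asarray(self.y_obs, dtype=float)
        w = np.asarray(self.died)
        V = np.atleast_2d(np.asarray(self.V, dtype=float))
        Xm = np.atleast_2d(np.asarray(self.X_marker, dtype=float))
        Xd = np.atleast_2d(np.asarray(self.X_death, dtype=float))
        n = y.shape[0]
        if n == 0:
            raise ValueError("empty dataset")
        for name, arr in (("V", V), ("X_marker", Xm), ("X_death", Xd)):
            if arr.shape[0] != n:
                raise ValueError(
                    f"{name} has {arr.shape[0]} rows, expected {n} (one per patient)"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite values in y_obs")
        if w.shape != (n,) or not np.isin(w, (0, 1)).all():
            raise ValueError("died must be an (n,) array of 0/1 indicators")
        ids = np.asarray(self.ids)
        if ids.shape != (n,):
            raise ValueError("ids must have one entry per patient")
        units = self.rbc_units
        if units is not None:
            units = np.asarray(units, dtype=float)
            if units.shape != (n,) or np.any(units <= 0):
                raise ValueError("rbc_units must be positive, one per patient")
        object.__setattr__(self, "y_obs", y)
        object.__setattr__(self, "died", w.astype(np.int8))
        object.__setattr__(self, "V", V)
        object.__setattr__(self, "X_marker", Xm)
        object.__setattr__(self, "X_death", Xd)
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "rbc_units", units)

    @property
    def n(self) -> int:
        return self.y_obs.shape[0]

    @property
    def d_v(self) -> int:
        return self.V.shape[1]

    @property
    def d_xm(self) -> int:
        return self.X_marker.shape[1]

    @property
    def d_xd(self) -> int:
        return self.X_death.shape[1]

    @classmethod
    def from_records(cls, records: Sequence[PatientRecord]) -> "TraumaData":
        if len(records) == 0:
            raise ValueError("empty record collection")
        V = np.vstack([r.v for r in records])
        Xm = np.vstack([r.x for r in records])
        Xd = np.vstack([r.x if r.x_death is None else r.x_death for r in records])
        units = None
        if all(r.rbc_units is not None for r in records):
            units = np.array([r.rbc_units for r in records], dtype=float)
        return cls(
            y_obs=np.array([r.y_obs for r in records], dtype=float),
            died=np.array([r.w for r in records], dtype=int),
            V=V,
            X_marker=Xm,
            X_death=Xd,
            ids=np.array([r.id for r in records], dtype=object),
            rbc_units=units,
        )

    @classmethod
    def from_covariates(
        cls,
        y_obs,
        died,
        v_covariates,
        marker_covariates,
        death_covariates=None,
        ids=None,
        rbc_units=None,
        add_intercept: bool = True,
    ) -> "TraumaData":
        """Assemble a dataset from raw covariate columns.

        ``v_covariates`` etc. are (n, p) arrays *without* intercept when
        ``add_intercept`` is true (the default); a leading column of ones is
        prepended to each design matrix.
        """
        y = _as_1d(y_obs, "y_obs")
        n = y.shape[0]

        def design(cov):
            arr = np.asarray(cov, dtype=float)
            if arr.ndim == 1:
                arr = arr[:, None]
            if add_intercept:
                arr = np.column_stack([np.ones(arr.shape[0]), arr])
            return arr

        Xd = design(
            marker_covariates if death_covariates is None else death_covariates
        )
        if ids is None:
            ids = np.arange(n)
        return cls(
            y_obs=y,
            died=np.asarray(died),
            V=design(v_covariates),
            X_marker=design(marker_covariates),
            X_death=Xd,
            ids=np.asarray(ids),
            rbc_units=rbc_units,
        )

    def records(self) -> list[PatientRecord]:
        out = []
        for i in range(self.n):
            out.append(
                PatientRecord(
                    id=self.ids[i],
                    y_obs=float(self.y_obs[i]),
                    w=int(self.died[i]),
                    v=self.V[i],
                    x=self.X_marker[i],
                    x_death=self.X_death[i],
                    rbc_units=None if self.rbc_units is None else float(self.rbc_units[i]),
                )
            )
        return out


def as_data(data) -> TraumaData:
    """Coerce a TraumaData, a PatientRecord sequence, or a single record."""
    if isinstance(data, TraumaData):
        return data
    if isinstance(data, PatientRecord):
        return TraumaData.from_records([data])
    return TraumaData.from_records(list(data))


@dataclasses.dataclass(frozen=True)
class ModelParameters:
    """Complete parameter set of the joint latent-class model.

    ``alpha`` holds the multinomial-logit membership coefficients for classes
    1..K-1 with class K as the reference (shape (K-1, d_v); empty for K = 1).
    ``betas``/``gammas`` stack the class-specific marker and mortality
    coefficients row-wise.  A single residual SD ``sigma`` is shared across
    classes (unequal variances make the mixture likelihood unbounded).
    """

    alpha: np.ndarray
    betas: np.ndarray
    gammas: np.ndarray
    sigma: float

    def __post_init__(self):
        alpha = np.atleast_2d(np.asarray(self.alpha, dtype=float))
        betas = np.atleast_2d(np.asarray(self.betas, dtype=float))
        gammas = np.atleast_2d(np.asarray(self.gammas, dtype=float))
        K = betas.shape[0]
        if np.asarray(self.alpha).size == 0:
            alpha = np.zeros((0, alpha.shape[1] if alpha.ndim == 2 else 0))
        if gammas.shape[0] != K:
            raise ValueError(
                f"gammas has {gammas.shape[0]} rows but betas implies K={K}"
            )
        if alpha.shape[0] != K - 1:
            raise ValueError(
                f"alpha must have K-1={K - 1} rows (reference class last), "
                f"got {alpha.shape[0]}"
            )
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be positive, got {self.sigma!r}")
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "betas", betas)
        object.__setattr__(self, "gammas", gammas)
        object.__setattr__(self, "sigma", float(self.sigma))

    @property
    def K(self) -> int:
        return self.betas.shape[0]

    @property
    def d_v(self) -> int:
        return self.alpha.shape[1] if self.alpha.size else self.alpha.shape[1]

    @property
    def n_params(self) -> int:
        return (
            self.alpha.size + self.betas.size + self.gammas.size + 1
        )

    def full_alpha(self) -> np.ndarray:
        """(K, d_v) logit coefficients with the reference row of zeros appended."""
        d_v = self.alpha.shape[1]
        return np.vstack([self.alpha, np.zeros((1, d_v))])

    def permuted(self, perm: Sequence[int]) -> "ModelParameters":
        """Relabel classes by ``perm`` (new class j = old class perm[j]).

        The multinomial logits are re-expressed against the new reference
        (the last class after permutation), leaving every membership
        probability, and hence the likelihood, unchanged.
        """
        perm = list(perm)
        if sorted(perm) != list(range(self.K)):
            raise ValueError(f"perm must be a permutation of 0..{self.K - 1}")
        A = self.full_alpha()[perm]
        A = A - A[-1]
        return ModelParameters(
            alpha=A[:-1],
            betas=self.betas[perm],
            gammas=self.gammas[perm],
            sigma=self.sigma,
        )

    def canonical(self) -> tuple["ModelParameters", np.ndarray]:
        """Sort classes by descending marker intercept (class 1 = SH)."""
        perm = np.argsort(-self.betas[:, 0], kind="stable")
        return self.permuted(perm), perm

    # ---- flattened view used by the inference machinery -------------------
    def flatten(self, log_sigma: bool = True) -> np.ndarray:
        s = math.log(self.sigma) if log_sigma else self.sigma
        return np.concatenate(
            [self.alpha.ravel(), self.betas.ravel(), self.gammas.ravel(), [s]]
        )

    def param_names(self) -> list[str]:
        names = []
        for k in range(self.K - 1):
            for j in range(self.alpha.shape[1]):
                names.append(f"alpha{j}" if self.K == 2 else f"alpha{j}[{k + 1}]")
        for k in range(self.K):
            for j in range(self.betas.shape[1]):
                names.append(f"beta{j}[{k + 1}]")
        for k in range(self.K):
            for j in range(self.gammas.shape[1]):
                names.append(f"gamma{j}[{k + 1}]")
        names.append("log_sigma")
        return names

    @classmethod
    def from_flat(
        cls, theta, K: int, d_v: int, d_xm: int, d_xd: int, log_sigma: bool = True
    ) -> "ModelParameters":
        theta = np.asarray(theta, dtype=float)
        expected = (K - 1) * d_v + K * (d_xm + d_xd) + 1
        if theta.shape != (expected,):
            raise ValueError(
                f"flattened parameter vector has length {theta.size}, "
                f"expected {expected}"
            )
        pos = 0
        alpha = theta[pos : pos + (K - 1) * d_v].reshape(K - 1, d_v)
        pos += (K - 1) * d_v
        betas = theta[pos : pos + K * d_xm].reshape(K, d_xm)
        pos += K * d_xm
        gammas = theta[pos : pos + K * d_xd].reshape(K, d_xd)
        pos += K * d_xd
        s = math.exp(theta[pos]) if log_sigma else theta[pos]
        return cls(alpha=alpha, betas=betas, gammas=gammas, sigma=s)


@dataclasses.dataclass(frozen=True)
class LatentState:
    """E-step quantities: posterior memberships and censored-marker moments.

    ``g`` is the (n, K) matrix of posterior class probabilities.  ``z_mean``
    and ``z_sq`` hold the conditional first and second moments of the
    uncensored log marker for censored (died) records; rows with ``died == 0``
    are NaN by construction.
    """

    g: np.ndarray
    z_mean: np.ndarray
    z_sq: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.g, dtype=float)
        if g.ndim != 2:
            raise ValueError("g must be an (n, K) matrix")
        if np.any(g < -1e-12) or np.any(g > 1 + 1e-12):
            raise ValueError("posterior probabilities must lie in [0, 1]")
        rows = g.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-8):
            raise ValueError("posterior rows must sum to 1")
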