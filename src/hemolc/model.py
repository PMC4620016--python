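"""Model/Results interface to the joint latent-class mixture.

``JointLatentClassModel`` wraps a patient-level dataset and a class count;
``fit()`` runs multi-start EM and returns a ``JointLatentClassResults``
carrying the estimates, empirical-information standard errors, BIC,
posterior classification and a text ``summary()``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import (
    BandScheme,
    classify_posteriors,
    compare_sh_mt,
    default_bands,
    mt_rule,
)
from .data import ModelParameters, TraumaData, as_data
from .em import EMConfig, FitResult, bic_scan, fit_em, posterior_membership
from .inference import InferenceResult, compute_inference, wald_tests
from .likelihood import observed_loglik

__all__ = ["JointLatentClassModel", "JointLatentClassResults"]


class JointLatentClassModel:
    """Joint latent-class model for a death-censored marker and 24-h survival.

    Parameters
    ----------
    data : TraumaData or sequence of PatientRecord
        Observations: log cumulative RBC units by min(24 h, death), the
        death indicator, and the membership / class-specific design matrices.
    n_classes : int
        Number of latent classes K (class 1 is reported as the severe-
        hemorrhage class after canonical ordering by marker intercept).

    Examples
    --------
    >>> from hemolc import SimScenario, simulate_dataset
    >>> data, _ = simulate_dataset(SimScenario(n=500, sigma=0.5, seed=1))
    >>> res = JointLatentClassModel(data, n_classes=2).fit(seed=1)
    >>> round(res.bic, 1)  # doctest: +SKIP
    """

    def __init__(self, data, n_classes: int = 2):
        if n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        self.data: TraumaData = as_data(data)
        self.n_classes = int(n_classes)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        membership,
        class_specific=None,
        marker=None,
        death=None,
        units_col: str = "rbc_units_24h",
        death_col: str = "death_24h",
        id_col: str | None = "id",
        n_classes: int = 2,
    ) -> "JointLatentClassModel":
        """Build the model from a patient-level DataFrame.

        ``membership`` names the covariate columns of the class-membership
        model; ``class_specific`` those shared by the marker and mortality
        models (or give ``marker``/``death`` separately).  The marker is
        log(units); intercepts are prepended automatically.
        """
        marker_cols = list(marker if marker is not None else class_specific or [])
        death_cols = list(death if death is not None else class_specific or [])
        units = df[units_col].to_numpy(dtype=float)
        if np.any(units <= 0):
            raise ValueError(f"{units_col} must be positive")
        data = TraumaData.from_covariates(
            y_obs=np.log(units),
            died=df[death_col].to_numpy(),
            v_covariates=df[list(membership)].to_numpy(dtype=float),
            marker_covariates=df[marker_cols].to_numpy(dtype=float),
            death_covariates=df[death_cols].to_numpy(dtype=float),
            ids=df[id_col].to_numpy() if id_col and id_col in df else None,
            rbc_units=units,
        )
        return cls(data, n_classes=n_classes)

    def loglike(self, params: ModelParameters) -> float:
        """Observed-data log-likelihood at ``params``."""
        return observed_loglik(self.data, params)

    def fit(
        self,
        n_starts: int = 20,
        max_iter: int = 2000,
        tol: float = 1e-8,
        seed: int = 0,
        compute_se: bool = True,
        config: EMConfig | None = None,
    ) -> "JointLatentClassResults":
        """Maximum likelihood by multi-start EM; see ``em.fit_em``."""
        cfg = config or EMConfig(
            n_starts=n_starts, max_iter=max_iter, tol=tol, seed=seed
        )
        mle = fit_em(self.data, self.n_classes, cfg)
        inference = compute_inference(self.data, mle.params) if compute_se else None
        return JointLatentClassResults(self, mle, inference)

    def select_n_classes(self, k_range=(1, 2, 3), config: EMConfig | None = None):
        """BIC table over candidate class counts (argmin-BIC row flagged)."""
        return bic_scan(self.data, k_range, config)


class JointLatentClassResults:
    """Fitted joint latent-class model."""

    def __init__(
        self,
        model: JointLatentClassModel,
        mle: FitResult,
        inference: InferenceResult | None = None,
    ):
        self.model = model
        self.mle = mle
        self.inference = inference

    # ---- statsmodels-flavoured accessors ----------------------------------
    @property
    def params(self) -> pd.Series:
        """Flattened estimates (alpha, beta, gamma rows, log sigma)."""
        p = self.mle.params
        return pd.Series(p.flatten(log_sigma=True), index=p.param_names())

    @property
    def bse(self) -> pd.Series:
        self._require_inference()
        return pd.Series(self.inference.se, index=self.inference.names)

    @property
    def pvalues(self) -> pd.Series:
        self._require_inference()
        return pd.Series(self.inference.p_values, index=self.inference.names)

    @property
    def llf(self) -> float:
        return self.mle.loglik

    @property
    def bic(self) -> float:
        return self.mle.bic

    @property
    def sigma(self) -> float:
        return self.mle.params.sigma

    def cov_params(self) -> pd.DataFrame:
        self._require_inference()
        return pd.DataFrame(
            self.inference.cov,
            index=self.inference.names,
            columns=self.inference.names,
        )

    def _require_inference(self):
        if self.inference is None:
            raise ValueError("fit was run with compute_se=False")

    # ---- classification ---------------------------------------------------
    def posterior_probabilities(self) -> pd.DataFrame:
        g = posterior_membership(self.model.data, self.mle.params)
        return pd.DataFrame(
            g,
            columns=[f"class_{k + 1}" for k in range(self.mle.params.K)],
            index=pd.Index(self.model.data.ids, name="id"),
        )

    def classify(
        self, scheme: BandScheme | None = None, mt_threshold: float = 10.0
    ) -> pd.DataFrame:
        """Per-patient classification table.

        For K = 2: the class-1 (SH) posterior, its band label and the hard
        SH indicator; plus the conventional MT indicator when observed
        units are available.  For K > 2 only the argmax class is assigned
        (the band scheme applies to a single posterior).
        """
        g = posterior_membership(self.model.data, self.mle.params)
        if self.mle.params.K == 2:
            out = classify_posteriors(g[:, 0], scheme or default_bands())
        else:
            out = pd.DataFrame(
                {"assigned_class": np.argmax(g, axis=1) + 1}
            )
        out.index = pd.Index(self.model.data.ids, name="id")
        units = self.model.data.rbc_units
        if units is None:
            units = np.exp(self.model.data.y_obs)
        out["mt"] = mt_rule(units, threshold=mt_threshold)
        return out

    def sh_mt_comparison(self, mt_threshold: float = 10.0):
        """2x2 agreement of the hard SH label against the MT rule (K = 2)."""
        table = self.classify(mt_threshold=mt_threshold)
        if "sh" not in table:
            raise ValueError("SH/MT comparison is defined for K = 2 models")
        return compare_sh_mt(table["sh"].to_numpy(), table["mt"].to_numpy())

    def wald_table(self) -> pd.DataFrame:
        self._require_inference()
        return wald_tests(self.inference)

    # ---- reporting --------------------------------------------------------
    def summary(self) -> str:
        p = self.mle.params
        lines = [
            "Joint latent-class mixture model",
            "=" * 64,
            f"No. observations: {self.mle.n_obs:>6d}    Classes (K): {p.K}",
            f"Log-likelihood:   {self.llf:>12.4f}    BIC: {self.bic:.1f}",
            f"Converged: {self.mle.converged}  (iter {self.mle.n_iter}, "
            f"best of start {self.mle.start_index})",
            f"sigma: {p.sigma:.4f}",
            "-" * 64,
        ]
        if self.inference is not None:
            tab = self.wald_table()
            lines.append(f"{'parameter':<14}{'estimate':>10}{'se':>10}{'z':>8}{'P>|z|':>9}")
            for _, row in tab.iterrows():
                lines.append(
                    f"{row['parameter']:<14}{row['estimate']:>10.4f}"
                    f"{row['se']:>10.4f}{row['z']:>8.2f}{row['p_value']:>9.4f}"
                )
        else:
            for name, val in self.params.items():
                lines.append(f"{name:<14}{val:>10.4f}")
        lines.append("=" * 64)
        return "\n".join(lines)

    def plot_posterior(self, ax=None, bands: bool = True):
        """Histogram of the class-1 (SH) posterior with band boundaries."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        g = posterior_membership(self.model.data, self.mle.params)
        ax.hist(g[:, 0], bins=40, range=(0, 1), color="#4878b0", alpha=0.85)
        if bands and self.mle.params.K == 2:
            for b in default_bands().bands[:-1]:
                ax.axvline(b.lower, color="grey", lw=0.6, ls="--")
        ax.set_xlabel("posterior P(severe hemorrhage)")
        ax.set_ylabel("patients")
        return ax

    def __repr__(self):
        return (
            f"<JointLatentClassResults K={self.mle.params.K} "
            f"llf={self.llf:.2f} bic={self.bic:.1f} converged={self.mle.converged}>"
        )
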