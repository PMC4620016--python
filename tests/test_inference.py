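"""Empirical-information scores, covariance and Wald tests."""


import numpy as np
import pytest

from hemolc import (
    EMConfig,
    InferenceResult,
    ModelParameters,
    SimScenario,
    TraumaData,
    compute_inference,
    empirical_information,
    fit_em,
    individual_scores,
    observed_loglik,
    simulate_dataset,
    wald_tests,
)


def numerical_gradient(data, params, h=1e-6):
    """Central finite differences of the observed log-likelihood over the
    flattened parameters (log-sigma parameterization)."""
    theta = params.flatten(log_sigma=True)
    dims = dict(
        K=params.K, d_v=params.alpha.shape[1],
        d_xm=params.betas.shape[1], d_xd=params.gammas.shape[1],
    )
    grad = np.empty_like(theta)
    for j in range(theta.size):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        grad[j] = (
            observed_loglik(data, ModelParameters.from_flat(tp, **dims))
            - observed_loglik(data, ModelParameters.from_flat(tm, **dims))
        ) / (2 * h)
    return grad


def random_instance(rng, n=8, K=2):
    """Random small dataset + random parameters of matching dimensions."""
    V = np.column_stack([np.ones(n), rng.standard_normal(n)])
    Xm = np.column_stack([np.ones(n), rng.standard_normal(n), rng.random(n) < 0.5])
    Xd = np.column_stack([np.ones(n), Xm[:, 2]])
    data = TraumaData(
        y_obs=rng.normal(1.5, 1.0, n),
        died=(rng.random(n) < 0.4).astype(int),
        V=V, X_marker=Xm.astype(float), X_death=Xd.astype(float),
        ids=np.arange(n),
    )
    params = ModelParameters(
        alpha=rng.normal(0, 0.8, (K - 1, 2)),
        betas=rng.normal(1, 0.8, (K, 3)),
        gammas=rng.normal(0, 0.8, (K, 2)),
        sigma=float(rng.uniform(0.4, 1.5)),
    )
    return data, params


class TestScores:
    @pytest.mark.parametrize("seed", range(10))
    def test_fisher_identity_against_finite_differences(self, seed):
        """Summed conditional-expectation scores equal the observed-data
        gradient (Fisher's identity), at arbitrary parameter values."""
        rng = np.random.default_rng(seed)
        data, params = random_instance(rng)
        total = individual_scores(data, params).sum(axis=0)
        fd = numerical_gradient(data, params)
        np.testing.assert_allclose(total, fd, rtol=2e-5, atol=2e-5)

    def test_score_sums_to_zero_at_mle(self, benchmark_data):
        data, _ = benchmark_data
        fit = fit_em(data, 2, EMConfig(n_starts=3, tol=1e-10, max_iter=4000, seed=1))
        total = individual_scores(data, fit.params).sum(axis=0)
        assert np.max(np.abs(total)) < 1e-4 * data.n

    def test_k1_no_censoring_matches_textbook_formulas(self):
        rng = np.random.default_rng(3)
        n = 50
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        beta = np.array([1.0, -0.5])
        sigma = 0.8
        y = X @ beta + sigma * rng.standard_normal(n)
        data = TraumaData(
            y_obs=y, died=np.zeros(n, dtype=int), V=np.ones((n, 1)),
            X_marker=X, X_death=X, ids=np.arange(n),
        )
        params = ModelParameters(
            alpha=np.zeros((0, 1)), betas=beta[None, :],
            gammas=np.array([[0.2, 0.1]]), sigma=sigma,
        )
        S = individual_scores(data, params)
        resid = y - X @ beta
        np.testing.assert_allclose(S[:, 0:2], X * (resid / sigma**2)[:, None], rtol=1e-12)
        # d/dlog sigma of the Gaussian: -1 + resid^2/sigma^2
        np.testing.assert_allclose(S[:, -1], -1 + resid**2 / sigma**2, rtol=1e-12)


class TestInformation:
    def test_information_symmetric_psd(self, tiny_data, small_params):
        info = empirical_information(tiny_data, small_params)
        assert np.array_equal(info, info.T)
        assert np.linalg.eigvalsh(info).min() > -1e-8

    def test_logistic_se_close_to_glm_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(12)
        n = 2000
        X = np.column_stack([np.ones(n), (rng.random(n) < 0.5).astype(float)])
        gamma = np.array([-0.5, 1.0])
        w = (rng.random(n) < 1 / (1 + np.exp(-X @ gamma))).astype(int)
        beta = np.array([1.0, 0.3])
        y = X @ beta + 0.6 * rng.standard_normal(n)
        # dead patients' markers are uniform-censored, as the model assumes,
        # so the mortality block stays orthogonal to the marker block
        y = y + np.where(w == 1, np.log(rng.random(n)), 0.0)
        data = TraumaData(
            y_obs=y, died=w, V=np.ones((n, 1)),
            X_marker=X, X_death=X, ids=np.arange(n),
        )
        fit = fit_em(data, 1, EMConfig(n_starts=1, tol=1e-12, max_iter=5000, seed=0))
        inf = compute_inference(data, fit.params)
        ref = sm.Logit(w, X).fit(disp=0)
        ours = inf.se[-3:-1]  # gamma block precedes log_sigma
        np.testing.assert_allclose(ours, ref.bse, rtol=0.05)

    def test_singular_information_warns_and_flags(self):
        # duplicated covariate column makes the design rank deficient
        rng = np.random.default_rng(4)
        n = 60
        x = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x, x])
        data = TraumaData(
            y_obs=rng.normal(1, 1, n), died=np.zeros(n, dtype=int),
            V=np.ones((n, 1)), X_marker=X, X_death=X, ids=np.arange(n),
        )
        params = ModelParameters(
            alpha=np.zeros((0, 1)), betas=np.array([[1.0, 0.2, 0.2]]),
            gammas=np.array([[0.1, 0.1, 0.1]]), sigma=1.0,
        )
        with pytest.warns(RuntimeWarning, match="singular"):
            inf = compute_inference(data, params)
        assert inf.singular


class TestWald:
    def test_zero_estimate_gives_p_one(self):
        inf = InferenceResult(
            estimates=np.array([0.0, 1.0]), names=["a", "b"],
            cov=np.diag([0.25, 0.25]), se=np.array([0.5, 0.5]),
            wald_z=np.array([0.0, 2.0]), p_values=np.array([1.0, 0.0455]),
        )
        table = wald_tests(inf)
        assert table.loc[0, "p_value"] == pytest.approx(1.0)

    def test_1p96_se_gives_p_005(self, benchmark_data):
        data, _ = benchmark_data
        fit = fit_em(data, 2, EMConfig(n_starts=2, tol=1e-7, seed=0))
        inf = compute_inference(data, fit.params)
        table = wald_tests(inf)
        np.testing.assert_allclose(
            table["z"], table["estimate"] / table["se"], rtol=1e-12
        )
        from scipy.stats import norm

        np.testing.assert_allclose(
            table["p_value"], 2 * norm.sf(np.abs(table["z"])), rtol=1e-12
        )
        # sanity: a z of exactly 1.96 maps to p ~ 0.05
        assert 2 * norm.sf(1.96) == pytest.approx(0.05, abs=1e-3)
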