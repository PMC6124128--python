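"""GLS core: covariance assembly, profile likelihood, ML fitting."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from phylospatial.gls_core import (
    CollinearityError,
    CovarianceModel,
    FitOptions,
    ModelSpec,
    assemble_covariance,
    autocorrelation_contribution,
    fit_gls,
    fit_ols,
    gls_profile_loglik,
)


def random_spd(n, rng):
    A = rng.standard_normal((n, n))
    V = A @ A.T + n * np.eye(n)
    d = np.sqrt(np.diag(V))
    return V / np.outer(d, d)


class TestAssembleCovariance:
    def setup_method(self):
        rng = np.random.default_rng(1)
        self.P = random_spd(6, rng)
        self.S = random_spd(6, rng)

    def test_zero_weights_give_identity(self):
        cov = CovarianceModel(w_p=0.0, w_s=0.0)
        assert np.allclose(assemble_covariance(self.P, self.S, cov), np.eye(6))

    def test_pure_phylogenetic(self):
        cov = CovarianceModel(w_p=1.0, w_s=0.0)
        assert np.allclose(assemble_covariance(self.P, self.S, cov), self.P)

    def test_mixture_matches_direct_arithmetic(self):
        cov = CovarianceModel(w_p=0.3, w_s=0.5)
        expected = 0.3 * self.P + 0.5 * self.S + 0.2 * np.eye(6)
        V = assemble_covariance(self.P, self.S, cov)
        assert np.allclose(V, expected, atol=1e-12)
        assert np.allclose(np.diag(V), 1.0, atol=1e-9)

    def test_paper_mode_no_identity_component(self):
        cov = CovarianceModel(w_p=0.3, w_s=0.7, mode="paper")
        expected = 0.3 * self.P + 0.7 * self.S
        assert np.allclose(assemble_covariance(self.P, self.S, cov), expected)

    def test_dimension_mismatch_rejected(self):
        cov = CovarianceModel(w_p=0.3, w_s=0.3)
        with pytest.raises(ValueError, match="dimension"):
            assemble_covariance(self.P, self.S[:4, :4], cov)

    def test_weights_outside_simplex_rejected(self):
        with pytest.raises(ValueError):
            CovarianceModel(w_p=0.7, w_s=0.5)
        with pytest.raises(ValueError):
            CovarianceModel(w_p=-0.1, w_s=0.5)


class TestProfileLoglik:
    def test_ols_reduction_matches_statsmodels(self, rng):
        # V = I must agree with an independent OLS/ML implementation
        for _ in range(20):
            n, k = 25, 3
            X = np.column_stack([np.ones(n), rng.standard_normal((n, k - 1))])
            y = X @ rng.standard_normal(k) + rng.standard_normal(n)
            pf = gls_profile_loglik(y, X, np.eye(n))
            ols = sm.OLS(y, X).fit()
            assert np.allclose(pf.beta, ols.params, atol=1e-8)
            assert pf.loglik == pytest.approx(ols.llf, abs=1e-8)
            # s.e. uses the ML scale (rss/n), statsmodels uses rss/(n-k)
            assert np.allclose(
                pf.se, ols.bse * np.sqrt((n - k) / n), atol=1e-8
            )

    def test_loglik_matches_mvn_density(self, rng):
        # direct multivariate-normal density oracle at (beta_hat, sigma2_hat V)
        for _ in range(10):
            n = 8
            V = random_spd(n, rng)
            X = np.column_stack([np.ones(n), rng.standard_normal(n)])
            y = rng.standard_normal(n)
            pf = gls_profile_loglik(y, X, V)
            oracle = stats.multivariate_normal.logpdf(
                y, mean=X @ pf.beta, cov=pf.sigma2 * V
            )
            assert pf.loglik == pytest.approx(oracle, abs=1e-8)

    def test_exact_fit_guarded(self):
        x = np.arange(10.0)
        y = 2.0 * x
        X = x[:, None]
        with pytest.warns(UserWarning, match="floor"):
            pf = gls_profile_loglik(y, X, np.eye(10))
        assert pf.beta[0] == pytest.approx(2.0)
        assert np.isfinite(pf.loglik)

    def test_collinear_design_rejected(self, rng):
        x = rng.standard_normal(20)
        X = np.column_stack([np.ones(20), x, 2 * x])
        with pytest.raises(CollinearityError, match="offending"):
            gls_profile_loglik(rng.standard_normal(20), X, np.eye(20), ["c", "x", "x2"])

    def test_permutation_invariance(self, rng):
        n = 12
        V = random_spd(n, rng)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal(n)
        perm = rng.permutation(n)
        pf1 = gls_profile_loglik(y, X, V)
        pf2 = gls_profile_loglik(y[perm], X[perm], V[np.ix_(perm, perm)])
        assert pf1.loglik == pytest.approx(pf2.loglik, abs=1e-9)
        assert np.allclose(pf1.beta, pf2.beta, atol=1e-9)


class TestFitOls:
    def test_exact_line_recovered(self):
        x = np.linspace(0, 1, 20)
        traits = pd.DataFrame(
            {"x": x, "y": 3.0 + 0.5 * x + 0.01 * np.sin(99 * x)},
            index=[f"s{i}" for i in range(20)],
        )
        fit = fit_ols(ModelSpec("y", ("x",)), traits)
        assert fit.coef("(Intercept)")["beta"] == pytest.approx(3.0, abs=0.01)
        assert fit.coef("x")["beta"] == pytest.approx(0.5, abs=0.05)
        assert fit.df_resid == 18

    def test_row_order_invariance(self, rng):
        traits = pd.DataFrame(
            {"x": rng.standard_normal(15), "y": rng.standard_normal(15)},
            index=[f"s{i}" for i in range(15)],
        )
        f1 = fit_ols(ModelSpec("y", ("x",)), traits)
        f2 = fit_ols(ModelSpec("y", ("x",)), traits.sample(frac=1, random_state=0))
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-10)
        assert np.allclose(f1.params["beta"], f2.params["beta"], atol=1e-10)

    def test_listwise_deletion(self, rng):
        traits = pd.DataFrame(
            {"x": rng.standard_normal(15), "y": rng.standard_normal(15)},
            index=[f"s{i}" for i in range(15)],
        )
        traits.loc["s3", "x"] = np.nan
        fit = fit_ols(ModelSpec("y", ("x",)), traits)
        assert fit.n == 14
        assert "s3" not in fit.societies


class TestFitGls:
    def test_fixed_parameters_equal_single_profile_call(self, small_geometry, rng):
        P, D, _ = small_geometry
        ids = list(P.index)
        traits = pd.DataFrame(
            {"x": rng.standard_normal(30), "y": rng.standard_normal(30)}, index=ids
        )
        opts = FitOptions(w_p=0.4, w_s=0.3, sigma_s=1200.0)
        fit = fit_gls(ModelSpec("y", ("x",)), traits, P, D, opts)
        S = np.exp(-((D.to_numpy() / 1200.0) ** 2))
        V = 0.4 * P.to_numpy() + 0.3 * S + 0.3 * np.eye(30)
        X = np.column_stack([np.ones(30), traits["x"]])
        pf = gls_profile_loglik(traits["y"].to_numpy(), X, V)
        assert fit.loglik == pytest.approx(pf.loglik, abs=1e-10)
        assert np.allclose(fit.params["beta"], pf.beta, atol=1e-10)

    def test_nugget_loglik_at_least_ols(self, small_geometry, rng):
        # OLS is nested in the nugget mixture, so ML can only improve
        P, D, _ = small_geometry
        traits = pd.DataFrame(
            {"x": rng.standard_normal(30), "y": rng.standard_normal(30)},
            index=list(P.index),
        )
        spec = ModelSpec("y", ("x",))
        ols = fit_ols(spec, traits)
        gls = fit_gls(spec, traits, P, D, FitOptions(restarts=3))
        assert gls.loglik >= ols.loglik - 1e-6

    def test_aic_identity(self, small_geometry, rng):
        P, D, _ = small_geometry
        traits = pd.DataFrame(
            {"x": rng.standard_normal(30), "y": rng.standard_normal(30)},
            index=list(P.index),
        )
        fit = fit_gls(ModelSpec("y", ("x",)), traits, P, D, FitOptions(restarts=2))
        assert fit.aic == pytest.approx(
            2 * (fit.k + fit.n_free_cov) - 2 * fit.loglik
        )

    def test_paper_mode_weights_on_simplex_face(self, small_geometry, rng):
        # no identity component: w_p + w_s = 1 in the fitted model
        P, D, _ = small_geometry
        traits = pd.DataFrame(
            {"x": rng.standard_normal(30), "y": rng.standard_normal(30)},
            index=list(P.index),
        )
        fit = fit_gls(
            ModelSpec("y", ("x",)), traits, P, D,
            FitOptions(mode="paper", restarts=3),
        )
        assert fit.cov.mode == "paper"
        assert fit.cov.w_p + fit.cov.w_s == pytest.approx(1.0)
        assert np.isfinite(fit.loglik)
        # one fewer free covariance parameter than the nugget mixture
        assert fit.n_free_cov == 3

    def test_too_few_cases_rejected(self, small_geometry, rng):
        P, D, _ = small_geometry
        traits = pd.DataFrame(
            {"x": rng.standard_normal(30), "y": rng.standard_normal(30)},
            index=list(P.index),
        )
        traits.iloc[5:, 0] = np.nan
        with pytest.raises(ValueError, match="complete cases"):
            fit_gls(ModelSpec("y", ("x",)), traits, P, D)


class TestContribution:
    def test_worked_examples(self):
        assert autocorrelation_contribution(-13.202, -17.734) == pytest.approx(
            0.256, abs=5e-4
        )
        assert autocorrelation_contribution(-58.308, -46.469) == pytest.approx(
            -0.255, abs=5e-4
        )

    def test_equal_logliks_give_zero(self):
        assert autocorrelation_contribution(-12.5, -12.5) == 0.0

    def test_zero_uncorrected_rejected(self):
        with pytest.raises(ZeroDivisionError):
            autocorrelation_contribution(-1.0, 0.0)
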