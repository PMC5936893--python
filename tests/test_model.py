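"""The joint covariance model, GLS likelihood and grid search."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from psgls import (
    NotPositiveDefiniteError,
    combine_covariance,
    derived_weights,
    gls_fit,
    likelihood_ratio_test,
    make_dataset,
    profile_grid_fit,
)

unit = st.floats(min_value=0.0, max_value=1.0)


class TestWeights:
    @pytest.mark.parametrize(
        "lam,phi,lam_prime,gamma",
        [(0.5, 0.5, 0.25, 0.25), (1.0, 0.0, 1.0, 0.0), (0.0, 1.0, 0.0, 0.0)],
    )
    def test_examples(self, lam, phi, lam_prime, gamma):
        w = derived_weights(lam, phi)
        assert w.lam_prime == pytest.approx(lam_prime)
        assert w.gamma == pytest.approx(gamma)

    @settings(derandomize=True, max_examples=200)
    @given(unit, unit)
    def test_partition_sums_to_one(self, lam, phi):
        w = derived_weights(lam, phi)
        assert w.gamma + w.lam_prime + w.phi == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= w.gamma <= 1.0 and 0.0 <= w.lam_prime <= 1.0

    @pytest.mark.parametrize("lam,phi", [(-0.1, 0.0), (0.0, 1.2)])
    def test_out_of_range(self, lam, phi):
        with pytest.raises(ValueError):
            derived_weights(lam, phi)


class TestCombineCovariance:
    def setup_method(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal((5, 5))
        s = a @ a.T
        d = np.sqrt(np.diag(s))
        self.sigma = s / np.outer(d, d)
        b = rng.standard_normal((5, 5))
        sw = b @ b.T
        dw = np.sqrt(np.diag(sw))
        self.w = sw / np.outer(dw, dw)

    def test_gamma_one_gives_identity(self):
        v = combine_covariance(derived_weights(0.0, 0.0), self.sigma, self.w)
        np.testing.assert_allclose(v, np.eye(5))

    def test_pure_phylogeny(self):
        v = combine_covariance(derived_weights(1.0, 0.0), self.sigma, self.w)
        np.testing.assert_allclose(v, self.sigma)

    def test_even_mixture(self):
        v = combine_covariance(derived_weights(0.5, 0.5), self.sigma, self.w)
        expected = 0.25 * np.eye(5) + 0.25 * self.sigma + 0.5 * self.w
        np.testing.assert_allclose(v, expected)
        np.testing.assert_allclose(np.diag(v), 1.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shapes"):
            combine_covariance(derived_weights(0.5, 0.5), self.sigma, np.eye(4))


class TestGLSFit:
    def test_intercept_only_identity_is_mean(self):
        fit = gls_fit(np.array([1.0, 2.0, 3.0]), np.ones((3, 1)), np.eye(3))
        assert fit.beta[0] == pytest.approx(2.0)

    def test_reduces_to_ols(self, rng):
        """With V = I the GLS fit is OLS: beta, p and ML scale agree."""
        for _ in range(20):
            n, k = 25, 3
            X = np.column_stack([np.ones(n), rng.standard_normal((n, k - 1))])
            y = X @ rng.standard_normal(k) + rng.standard_normal(n)
            fit = gls_fit(y, X, np.eye(n))
            ols = sm.OLS(y, X).fit()
            np.testing.assert_allclose(fit.beta, ols.params, atol=1e-8)
            np.testing.assert_allclose(fit.p_values, ols.pvalues, atol=1e-8)
            np.testing.assert_allclose(fit.se, ols.bse, atol=1e-8)
            assert fit.sigma2 == pytest.approx(np.sum(ols.resid**2) / n, abs=1e-8)

    def test_loglik_is_mvn_density_at_mle(self, rng):
        """Profiled loglik equals the dense MVN log-density oracle."""
        for _ in range(10):
            n = 8
            a = rng.standard_normal((n, n))
            v = a @ a.T + n * np.eye(n)
            d = np.sqrt(np.diag(v))
            v = v / np.outer(d, d)
            X = np.column_stack([np.ones(n), rng.standard_normal(n)])
            y = rng.standard_normal(n)
            fit = gls_fit(y, X, v)
            oracle = stats.multivariate_normal.logpdf(
                y, mean=X @ fit.beta, cov=fit.sigma2 * v
            )
            assert fit.loglik == pytest.approx(oracle, abs=1e-6)

    def test_indefinite_v_error(self):
        v = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(NotPositiveDefiniteError):
            gls_fit(np.array([1.0, 2.0, 3.0]), np.ones((3, 1)), v)

    def test_collinear_design_error(self):
        X = np.column_stack([np.ones(5), np.ones(5)])
        with pytest.raises(np.linalg.LinAlgError, match="singular design"):
            gls_fit(np.arange(5.0), X, np.eye(5))

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="at least"):
            gls_fit(np.array([1.0, 2.0]), np.ones((2, 2)), np.eye(2))

    def test_near_psd_ridge_repair(self):
        """Eigenvalues barely below zero are ridged, not fatal."""
        q = np.linalg.qr(np.random.default_rng(0).standard_normal((4, 4)))[0]
        v = q @ np.diag([2.0, 1.0, 0.5, -1e-10]) @ q.T
        fit = gls_fit(np.array([1.0, 2.0, 3.0, 4.0]), np.ones((4, 1)), v)
        assert np.isfinite(fit.loglik)


class TestLikelihoodRatioTest:
    def test_equal_logliks_p_one(self):
        assert likelihood_ratio_test(-10.0, -10.0, df=1) == pytest.approx(1.0)

    @pytest.mark.parametrize("delta2,df", [(3.841, 1), (5.991, 2)])
    def test_five_percent_quantiles(self, delta2, df):
        p = likelihood_ratio_test(-10.0 + delta2 / 2.0, -10.0, df=df)
        assert p == pytest.approx(0.05, abs=5e-4)

    def test_non_nested_error(self):
        with pytest.raises(ValueError, match="not nested"):
            likelihood_ratio_test(-12.0, -10.0, df=1)

    def test_boundary_mixture_halves_tail(self):
        plain = likelihood_ratio_test(-8.0, -10.0, df=1)
        mix = likelihood_ratio_test(-8.0, -10.0, df=1, boundary_mixture=True)
        assert mix == pytest.approx(plain / 2.0)


@pytest.fixture(scope="module")
def dataset():
    return make_dataset(n_tips=20, lam=0.6, phi=0.2, sigma2=1.0, seed=42)


class TestGridFit:

    def test_grid_shape_both(self, dataset):
        res = profile_grid_fit(dataset.y, dataset.X, dataset.sigma_star, dataset.w)
        assert res.surface.shape == (51, 51)

    def test_surface_maximum_is_fit(self, dataset):
        res = profile_grid_fit(dataset.y, dataset.X, dataset.sigma_star, dataset.w)
        assert res.fit.loglik == pytest.approx(float(np.max(res.surface)), abs=1e-10)
        assert np.all(res.surface <= res.fit.loglik + 1e-10)

    def test_mode_nesting_monotone(self, dataset):
        lls = {}
        for mode in ("both", "lambda_only", "phi_only", "neither"):
            res = profile_grid_fit(
                dataset.y, dataset.X, dataset.sigma_star, dataset.w, mode=mode
            )
            lls[mode] = res.fit.loglik
        assert lls["both"] >= max(lls["lambda_only"], lls["phi_only"]) - 1e-8
        assert min(lls["lambda_only"], lls["phi_only"]) >= lls["neither"] - 1e-8

    def test_neither_is_single_point(self, dataset):
        res = profile_grid_fit(
            dataset.y, dataset.X, dataset.sigma_star, dataset.w, mode="neither"
        )
        assert res.surface.shape == (1, 1)
        assert res.weights.lam == 0.0 and res.weights.phi == 0.0

    def test_tie_break_prefers_null(self):
        """A constant-residual response ties the whole surface; (0,0) wins."""
        ds = make_dataset(n_tips=10, lam=0.0, phi=0.0, sigma2=0.0, seed=1, beta=1.0)
        y = ds.X[:, 0]  # exactly the intercept: zero residual everywhere
        res = profile_grid_fit(y + np.arange(10) * 0.0, ds.X, ds.sigma_star, ds.w)
        # degenerate but well-defined: first (smallest lam, then phi) argmax
        i, j = np.unravel_index(np.argmax(res.surface), res.surface.shape)
        assert res.weights.lam <= res.lam_grid[i] + 1e-12
        assert res.weights.phi <= res.phi_grid[j] + 1e-12

    def test_bad_step_rejected(self, dataset):
        with pytest.raises(ValueError, match="divide"):
            profile_grid_fit(
                dataset.y, dataset.X, dataset.sigma_star, dataset.w, step=0.03
            )

    def test_bad_mode_rejected(self, dataset):
        with pytest.raises(ValueError, match="mode"):
            profile_grid_fit(
                dataset.y, dataset.X, dataset.sigma_star, dataset.w, mode="all"
            )

    def test_indefinite_spatial_matrix_survives(self, dataset):
        """Grid points with non-PD V go to -inf; the fit still succeeds."""
        w_bad = dataset.w.copy()
        n = w_bad.shape[0]
        w_bad = 2.0 * w_bad - np.ones((n, n))  # strongly indefinite
        np.fill_diagonal(w_bad, 1.0)
        assert np.linalg.eigvalsh(w_bad)[0] < -0.1
        res = profile_grid_fit(dataset.y, dataset.X, dataset.sigma_star, w_bad)
        assert np.isfinite(res.fit.loglik)
        assert np.any(np.isneginf(res.surface))

    def test_lrt_pvalues_match_surface(self, dataset):
        res = profile_grid_fit(dataset.y, dataset.X, dataset.sigma_star, dataset.w)
        ll_lam = float(np.max(res.surface[:, 0]))
        expected = stats.chi2.sf(2.0 * (res.fit.loglik - ll_lam), 1)
        assert res.lrt_p["phi"] == pytest.approx(float(expected))
        assert set(res.lrt_p) == {"lambda", "phi", "joint"}
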