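"""Unit tests for the truncated negative-binomial core."""

import numpy as np
import pytest
from scipy import optimize, stats

import runner_burden as rb
from runner_burden.exceptions import (
    DomainError,
    IdentifiabilityError,
    NumericalError,
    SupportError,
)
from runner_burden.trunc_nb import tnb_logpmf


class TestNbPmf:
    def test_geometric_closed_form(self):
        # NB(mu=1, theta=1) is geometric with mass 0.5 ** (y + 1)
        for y in range(6):
            assert rb.nb_pmf(y, 1.0, 1.0) == pytest.approx(0.5 ** (y + 1), rel=1e-12)

    def test_normalization(self):
        total = rb.nb_pmf(np.arange(2001), 3.0, 2.0).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_poisson_limit(self):
        assert rb.nb_pmf(3, 2.0, 1e6) == pytest.approx(
            stats.poisson.pmf(3, 2.0), abs=1e-4
        )

    @pytest.mark.parametrize("bad_y", [-1, 1.5])
    def test_domain_errors(self, bad_y):
        with pytest.raises(DomainError):
            rb.nb_pmf(bad_y, 1.0, 1.0)

    def test_nonpositive_params(self):
        with pytest.raises(DomainError):
            rb.nb_pmf(1, -1.0, 1.0)
        with pytest.raises(DomainError):
            rb.nb_pmf(1, 1.0, 0.0)


class TestTnbPmf:
    def test_geometric_truncated(self):
        # f(1)=0.25 and 1 - f(0) = 0.5 for the geometric case
        assert rb.tnb_pmf(1, 1.0, 1.0, 0) == pytest.approx(0.5, rel=1e-12)

    def test_outside_support(self):
        with pytest.raises(SupportError):
            rb.tnb_pmf(0, 1.0, 1.0, 0)

    def test_normalization(self):
        total = rb.tnb_pmf(np.arange(3, 2001), 3.0, 2.0, 2).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_denominator_underflow_raises(self):
        # mu so small that even the log survival function underflows
        with pytest.raises(NumericalError):
            rb.tnb_pmf(6, 1e-60, 2.0, 5)


class TestLoglikAndGrad:
    def test_intercept_only_single_row(self):
        ll, _ = rb.tnb_loglik_and_grad(
            beta=[0.0], log_theta=0.0, X=[[1.0]], y=[1], t=0
        )
        assert ll == pytest.approx(np.log(0.5), rel=1e-12)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        n = 150
        X = np.column_stack([np.ones(n), rng.normal(0, 1, n)])
        y = rng.integers(2, 30, n)
        point = np.array([0.7, -0.3, np.log(1.7)])
        _, g = rb.tnb_loglik_and_grad(point[:2], point[2], X, y, t=1)
        fd = np.zeros(3)
        for i in range(3):
            e = np.eye(3)[i] * 1e-5
            up = rb.tnb_loglik_and_grad((point + e)[:2], (point + e)[2], X, y, 1)[0]
            dn = rb.tnb_loglik_and_grad((point - e)[:2], (point - e)[2], X, y, 1)[0]
            fd[i] = (up - dn) / 2e-5
        assert np.max(np.abs(g - fd) / (1 + np.abs(fd))) < 1e-5

    def test_empty_rows_error(self):
        with pytest.raises(DomainError):
            rb.tnb_loglik_and_grad([0.0], 0.0, np.empty((0, 1)), [], 0)

    def test_row_below_support_error(self):
        with pytest.raises(SupportError):
            rb.tnb_loglik_and_grad([0.0], 0.0, [[1.0]], [0], 0)


class TestFit:
    def test_parameter_recovery_one_predictor(self):
        rng = np.random.default_rng(7)
        n = 20000
        x1 = rng.normal(0, 1, n)
        mu = np.exp(1.0 + 0.5 * x1)
        y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
        keep = y > 0
        model = rb.fit_tnb_regression(x1[keep][:, None], y[keep], t=0)
        assert model.converged
        assert np.abs(model.beta - [1.0, 0.5]).max() < 0.05
        assert abs(model.theta - 2.0) / 2.0 < 0.1

    def test_matches_independent_zero_truncated_fit(self):
        from statsmodels.discrete.truncated_model import (
            TruncatedLFNegativeBinomialP,
        )

        rng = np.random.default_rng(21)
        n = 5000
        X = rng.normal(0, 1, (n, 2))
        mu = np.exp(0.8 + 0.4 * X[:, 0] - 0.3 * X[:, 1])
        y = rng.negative_binomial(3.0, 3.0 / (3.0 + mu))
        keep = y > 0
        model = rb.fit_tnb_regression(X[keep], y[keep], t=0)
        sm_design = np.column_stack([np.ones(keep.sum()), X[keep]])
        ref = TruncatedLFNegativeBinomialP(y[keep], sm_design, truncation=0).fit(
            method="bfgs", maxiter=1000, disp=0, gtol=1e-10
        )
        assert np.abs(model.beta - ref.params[:3]).max() < 1e-4
        assert abs(model.theta - 1.0 / ref.params[3]) < 1e-4 * model.theta

    def test_duplicate_column_raises(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 300)
        X = np.column_stack([x, x])
        y = rng.integers(1, 20, 300)
        with pytest.raises(IdentifiabilityError):
            rb.fit_tnb_regression(X, y, t=0)

    def test_constant_column_raises(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([rng.normal(0, 1, 300), np.full(300, 2.0)])
        y = rng.integers(1, 20, 300)
        with pytest.raises(IdentifiabilityError):
            rb.fit_tnb_regression(X, y, t=0)

    def test_too_few_rows(self):
        with pytest.raises(DomainError):
            rb.fit_tnb_regression(np.ones((5, 1)) + np.arange(5)[:, None],
                                  [1, 2, 3, 4, 5], t=0)

    def test_model_json_roundtrip(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 400)
        y = np.maximum(rng.poisson(np.exp(1 + 0.3 * x)), 1)
        model = rb.fit_tnb_regression(x[:, None], y, t=0)
        clone = rb.TNBModel.from_json(model.to_json())
        assert np.allclose(clone.beta, model.beta)
        assert clone.theta == pytest.approx(model.theta)
        assert clone.t == model.t


class TestPredictMu:
    def test_all_zero_coefficients(self):
        m = rb.TNBModel(beta=np.zeros(3), theta=1.0, t=0, converged=True,
                        loglik=0.0, n_fit=10)
        assert rb.predict_mu(m, [[5.0, -3.0]]) == pytest.approx(1.0)

    def test_intercept_log_two(self):
        m = rb.TNBModel(beta=np.array([np.log(2.0), 0.0]), theta=1.0, t=0,
                        converged=True, loglik=0.0, n_fit=10)
        assert rb.predict_mu(m, [[7.0]]) == pytest.approx(2.0)

    def test_single_slope(self):
        m = rb.TNBModel(beta=np.array([0.0, 1.0]), theta=1.0, t=0,
                        converged=True, loglik=0.0, n_fit=10)
        assert rb.predict_mu(m, [[0.5]]) == pytest.approx(np.exp(0.5), rel=1e-9)


class TestSaturatedMu:
    def test_untruncated_mode_is_observation(self):
        for y in (1, 5, 40):
            assert rb.saturated_mu(y, 2.0, -1) == y

    def test_zero_truncated_low_count_hits_boundary(self):
        # for y=1, t=0 the truncated likelihood increases as mu -> 0
        assert rb.saturated_mu(1, 1.0, 0) == pytest.approx(1e-8)

    def test_far_from_truncation_close_to_y(self):
        assert rb.saturated_mu(50, 5.0, 0) == pytest.approx(50.0, rel=0.01)

    @pytest.mark.parametrize("y,theta,t", [(4, 2.0, 1), (12, 0.7, 3), (30, 9.0, 5)])
    def test_against_dense_grid(self, y, theta, t):
        mu_grid = np.geomspace(1e-6, 10 * y, 30000)
        ll = tnb_logpmf(np.full(mu_grid.size, y), mu_grid, theta, t)
        best = mu_grid[np.argmax(ll)]
        opt = rb.saturated_mu(y, theta, t)
        ll_opt = tnb_logpmf(np.array([y]), opt, theta, t)[0]
        assert ll_opt >= ll.max() - 1e-8

    def test_below_support_error(self):
        with pytest.raises(SupportError):
            rb.saturated_mu(2, 1.0, 2)


class TestDevianceResidual:
    def test_zero_when_fitted_equals_saturated(self):
        mu_star = rb.saturated_mu(50, 5.0, 0)
        assert rb.deviance_residual(50, mu_star, 5.0, 0) == pytest.approx(0.0, abs=1e-4)

    def test_signs(self):
        assert rb.deviance_residual(12, 3.0, 2.0, 0) > 0
        assert rb.deviance_residual(2, 9.0, 2.0, 0) < 0

    def test_formula_recomputation(self):
        # e = sign(y - mu) * sqrt(2 |l(y|mu*) - l(y|mu)|), from raw log-pmf values
        y, mu_hat, theta, t = 12, 3.0, 2.0, 0
        mu_star = rb.saturated_mu(y, theta, t)
        l_star = np.log(rb.tnb_pmf(y, mu_star, theta, t))
        l_fit = np.log(rb.tnb_pmf(y, mu_hat, theta, t))
        expected = np.sign(y - mu_hat) * np.sqrt(2 * abs(l_star - l_fit))
        assert rb.deviance_residual(y, mu_hat, theta, t) == pytest.approx(
            expected, rel=1e-10
        )


class TestStandardize:
    def test_centre_gives_half(self):
        e = np.array([-1.0, 0.0, 1.0])
        _, p = rb.standardize_and_pvalue(e, np.array([0.0]))
        assert p[0] == pytest.approx(0.5)

    def test_95th_percentile(self):
        e_bg = np.array([-1.0, 1.0])  # mean 0, sd sqrt(2)
        z = 1.6449 * np.sqrt(2.0)
        _, p = rb.standardize_and_pvalue(e_bg, np.array([z]))
        assert p[0] == pytest.approx(0.05, abs=1e-4)

    def test_three_point_background(self):
        e_bg = np.array([-1.0, 0.0, 1.0])
        e_std, p = rb.standardize_and_pvalue(e_bg, np.array([1.0]))
        assert e_std[0] == pytest.approx(1.0)
        assert p[0] == pytest.approx(stats.norm.sf(1.0), rel=1e-9)

    def test_zero_variance_error(self):
        with pytest.raises(DomainError):
            rb.standardize_and_pvalue(np.ones(5), np.ones(5))


def test_null_model_pvalues_uniform_single_seed():
    """Counts drawn from the fitted null give ~uniform one-sided p-values."""
    cfg = rb.SimConfig(n_genes=15000, theta=2.0, seed=0)
    table, _ = rb.simulate_burden_table(cfg)
    fit = rb.recursive_fit(table, t=0)
    p = fit.scores.loc[fit.scores["in_support"], "p"].to_numpy()
    assert stats.kstest(p, "uniform").pvalue > 0.01
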