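"""Log-density components, covariance assembly and the LKJ machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

import dentbayes as db
from dentbayes.model import (
    cpc_to_cholesky,
    cholesky_to_cpc,
    expit,
    gamma_logpdf,
    halfcauchy_logpdf,
    lkj_log_norm,
    log1pexp,
    logit,
    mvn_logpdf,
)


class TestLinearPredictor:
    def test_zero_coefficients_give_zero_mean(self):
        mu = db.linear_predictor(np.ones(4), np.zeros((4, 3)), 0.0)
        np.testing.assert_array_equal(mu, np.zeros(3))

    def test_intercept_only_model_returns_intercepts(self):
        intercepts = np.array([[-1.235, -2.132, -0.383]])
        mu = db.linear_predictor(np.ones(1), intercepts, 0.0)
        np.testing.assert_allclose(mu, intercepts[0])

    def test_random_effect_shifts_every_component_equally(self, rng):
        beta = rng.standard_normal((5, 3))
        x = np.concatenate([[1.0], rng.standard_normal(4)])
        base = db.linear_predictor(x, beta, 0.0)
        np.testing.assert_allclose(db.linear_predictor(x, beta, 0.5), base + 0.5)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            db.linear_predictor(np.ones(3), np.zeros((4, 3)), 0.0)


class TestAssembleCovariance:
    def test_identity_case(self):
        np.testing.assert_array_equal(
            db.assemble_covariance(np.ones(3), np.eye(3)), np.eye(3)
        )

    def test_diagonal_scaling(self):
        sigma = db.assemble_covariance(np.array([2.0, 1.0, 1.0]), np.eye(3))
        np.testing.assert_array_equal(sigma, np.diag([4.0, 1.0, 1.0]))

    def test_off_diagonal_product(self):
        omega = np.array([[1.0, 0.5], [0.5, 1.0]])
        sigma = db.assemble_covariance(np.array([1.0, 2.0]), omega)
        assert sigma[0, 1] == pytest.approx(1.0)
        assert sigma[1, 1] == pytest.approx(4.0)

    def test_invalid_correlation_raises(self):
        bad = np.array([[1.0, 1.2], [1.2, 1.0]])
        with pytest.raises(ValueError):
            db.assemble_covariance(np.ones(2), bad)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_output_positive_definite_over_random_lkj_draws(self, seed):
        rng = np.random.default_rng(seed)
        omega = db.sample_lkj(3, 1.0, rng)
        tau = rng.uniform(0.1, 3.0, size=3)
        sigma = db.assemble_covariance(tau, omega)
        assert np.linalg.eigvalsh(sigma).min() > 0


class TestBernoulliLoglik:
    def _panel(self, y, mask):
        y = np.atleast_2d(np.asarray(y, dtype=float))
        mask = np.atleast_2d(np.asarray(mask, dtype=bool))
        return db.DefectPanel(
            list(range(y.shape[0])), y, mask, "regions", ("c", "m", "i")
        )

    def test_fair_coin_single_cell(self):
        panel = self._panel([[0, 0, 0]], [[True, False, False]])
        z = np.zeros((1, 3))
        assert db.bernoulli_loglik(panel, z) == pytest.approx(np.log(0.5))

    def test_saturated_cell_does_not_overflow(self):
        panel = self._panel([[1, 0, 0]], [[True, False, False]])
        z = np.array([[50.0, 0.0, 0.0]])
        assert db.bernoulli_loglik(panel, z) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_two_cell_case(self):
        panel = self._panel([[1, 0, 0]], [[True, True, False]])
        z = np.array([[1.0, -1.0, 0.0]])
        expected = -2.0 * np.log1p(np.exp(-1.0))
        assert db.bernoulli_loglik(panel, z) == pytest.approx(expected, rel=1e-10)

    def test_masked_cells_contribute_nothing(self, rng):
        y = (rng.random((6, 3)) < 0.5).astype(float)
        mask = rng.random((6, 3)) < 0.6
        panel = self._panel(y, mask)
        z = rng.standard_normal((6, 3))
        brute = sum(
            y[i, j] * z[i, j] - np.log1p(np.exp(z[i, j]))
            for i in range(6)
            for j in range(3)
            if mask[i, j]
        )
        assert db.bernoulli_loglik(panel, z) == pytest.approx(brute, rel=1e-12)


class TestLkj:
    def test_eta_one_density_constant_over_valid_matrices(self, rng):
        values = {
            round(db.lkj_logdensity(db.sample_lkj(3, 1.0, rng), eta=1.0), 12)
            for _ in range(5)
        }
        assert values == {0.0}

    def test_eta_two_difference_matches_determinant(self):
        omega = np.eye(3)
        omega2 = np.eye(3)
        omega2[0, 1] = omega2[1, 0] = 0.9
        diff = db.lkj_logdensity(omega, 2.0) - db.lkj_logdensity(omega2, 2.0)
        assert diff == pytest.approx(-np.log(1 - 0.9**2), rel=1e-10)

    def test_singular_matrix_rejected(self):
        omega = np.ones((2, 2))
        with pytest.raises(ValueError):
            db.lkj_logdensity(omega, 1.0)

    def test_marginal_correlation_matches_scaled_beta(self):
        # d=3, eta=1: off-diagonals are 2*Beta(1.5,1.5)-1
        rng = np.random.default_rng(42)
        draws = np.array([db.sample_lkj(3, 1.0, rng)[0, 1] for _ in range(5000)])
        ks = stats.kstest(draws, lambda q: stats.beta.cdf((q + 1) / 2, 1.5, 1.5))
        assert ks.pvalue > 0.01

    def test_normalizing_constant_d2_against_quadrature(self):
        for eta in (1.0, 2.0, 3.5):
            numeric, _ = integrate.quad(lambda r: (1 - r**2) ** (eta - 1), -1, 1)
            assert lkj_log_norm(2, eta) == pytest.approx(np.log(numeric), rel=1e-8)

    def test_cpc_round_trip(self, rng):
        omega = db.sample_lkj(4, 1.0, rng)
        L = np.linalg.cholesky(omega)
        z = cholesky_to_cpc(L)
        np.testing.assert_allclose(cpc_to_cholesky(z), L, atol=1e-10)


class TestScalarPriors:
    def test_gamma_2_rate_half_at_four_is_exactly_minus_two(self):
        assert gamma_logpdf(4.0, 2.0, 0.5) == pytest.approx(-2.0, abs=1e-12)

    def test_gamma_matches_scipy_shape_rate(self):
        xs = np.array([0.3, 1.0, 7.5])
        expected = stats.gamma.logpdf(xs, a=2.0, scale=2.0)
        np.testing.assert_allclose(gamma_logpdf(xs, 2.0, 0.5), expected, rtol=1e-12)

    def test_half_cauchy_mode_density(self):
        assert halfcauchy_logpdf(0.0, 2.5) == pytest.approx(
            np.log(2.0 / (np.pi * 2.5)), abs=1e-12
        )

    def test_half_cauchy_matches_scipy(self):
        xs = np.array([0.1, 1.0, 10.0])
        expected = stats.halfcauchy.logpdf(xs, scale=2.5)
        np.testing.assert_allclose(halfcauchy_logpdf(xs, 2.5), expected, rtol=1e-12)

    def test_nan_coefficient_raises(self):
        params = {"beta": np.array([[np.nan]]), "sigma2_beta": 1.0}
        with pytest.raises(ValueError):
            db.log_prior(params)

    def test_out_of_support_variance_is_minus_inf(self):
        params = {"beta": np.zeros((2, 3)), "sigma2_beta": -1.0}
        assert db.log_prior(params) == -np.inf


class TestExpitLogit:
    @given(p=st.floats(1e-9, 1 - 1e-9))
    @settings(max_examples=50, deadline=None)
    def test_expit_logit_identity(self, p):
        assert expit(logit(p)) == pytest.approx(p, abs=1e-12)

    def test_log1pexp_safe_at_extremes(self):
        assert np.isfinite(log1pexp(800.0))
        assert log1pexp(-800.0) == pytest.approx(0.0, abs=1e-12)


class TestMvnLogpdf:
    def test_matches_scipy_multivariate_normal(self, rng):
        sigma = db.assemble_covariance(
            np.array([1.0, 0.5, 2.0]), db.sample_lkj(3, 2.0, rng)
        )
        x = rng.standard_normal((7, 3))
        mean = rng.standard_normal(3)
        expected = stats.multivariate_normal.logpdf(x, mean, sigma).sum()
        assert mvn_logpdf(x, mean, sigma) == pytest.approx(expected, rel=1e-10)


def _random_state(rng, n=4, p=2, d=3):
    return {
        "z": rng.standard_normal((n, d)),
        "beta": rng.standard_normal((p + 1, d)),
        "sigma2_beta": float(rng.uniform(0.5, 3.0)),
        "b": rng.standard_normal(n),
        "sigma2_b": float(rng.uniform(0.5, 2.0)),
        "tau": rng.uniform(0.5, 2.0, size=d),
        "omega": db.sample_lkj(d, 1.0, rng),
        "indicator": (rng.random((p, d)) < 0.5).astype(float),
        "psi": rng.uniform(0.1, 0.9, size=(p, d)),
    }


class TestLogJoint:
    def _data(self, rng, n=4, p=2, d=3):
        y = (rng.random((n, d)) < 0.4).astype(float)
        mask = rng.random((n, d)) < 0.8
        panel = db.DefectPanel(list(range(n)), y, mask, "regions", ("c", "m", "i"))
        x = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
        return panel, x

    def test_component_sum_oracle_on_random_states(self, rng):
        # log_joint must equal the independently computed sum of its parts
        panel, x = self._data(rng)
        for _ in range(5):
            params = _random_state(rng)
            eff = db.effective_coefficients(params["beta"], params["indicator"])
            mu = x @ eff + params["b"][:, None]
            sigma = db.assemble_covariance(params["tau"], params["omega"])
            expected = (
                db.bernoulli_loglik(panel, params["z"])
                + mvn_logpdf(params["z"], mu, sigma)
                + db.log_prior(params)
            )
            assert db.log_joint(panel, x, params) == pytest.approx(
                expected, rel=1e-10
            )

    def test_all_masked_panel_reduces_to_mvn_plus_priors(self, rng):
        panel, x = self._data(rng)
        panel = db.DefectPanel(
            panel.subject_ids,
            panel.y,
            np.zeros_like(panel.observed_mask),
            "regions",
            panel.labels,
        )
        params = _random_state(rng)
        eff = db.effective_coefficients(params["beta"], params["indicator"])
        mu = x @ eff + params["b"][:, None]
        sigma = db.assemble_covariance(params["tau"], params["omega"])
        expected = mvn_logpdf(params["z"], mu, sigma) + db.log_prior(params)
        assert db.log_joint(panel, x, params) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_single_cell_matches_hand_computation(self):
        # one subject, one observed region cell; hand-computed parts
        y = np.array([[1.0, 0.0, 0.0]])
        mask = np.array([[True, False, False]])
        panel = db.DefectPanel([0], y, mask, "regions", ("c", "m", "i"))
        x = np.ones((1, 1))
        params = {
            "z": np.array([[0.4, 0.0, 0.0]]),
            "beta": np.array([[0.2, 0.0, 0.0]]),
            "sigma2_beta": 1.0,
            "tau": np.ones(3),
            "omega": np.eye(3),
        }
        # parts: Bernoulli cell, MVN at z (identity Sigma), beta prior at
        # (0.2, 0, 0), Gamma variance hyperprior, half-Cauchy at tau=1 (x3)
        by_hand = (
            (0.4 - np.log1p(np.exp(0.4)))
            + stats.norm.logpdf(0.4, 0.2, 1.0)
            + 2 * stats.norm.logpdf(0.0, 0.0, 1.0)
            + stats.norm.logpdf(0.2, 0.0, 1.0)
            + 2 * stats.norm.logpdf(0.0, 0.0, 1.0)
            + gamma_logpdf(1.0, 2.0, 0.5)
            + 3 * halfcauchy_logpdf(1.0, 2.5)
        )
        assert db.log_joint(panel, x, params) == pytest.approx(by_hand, rel=1e-10)
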