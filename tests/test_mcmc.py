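"""Sampler contracts, Gelman-Rubin, summaries and correlation conventions."""

import warnings

import numpy as np
import pytest
from scipy import stats

import dentbayes as db
from dentbayes.data import ColumnMeta, PredictorTable
from dentbayes.mcmc import ChainSet, McmcConfig
from dentbayes.model import ModelConfig, expit


def _empty_table(n):
    return PredictorTable(
        np.zeros((n, 0)), [], [], np.zeros((n, 0), dtype=bool)
    )


def _fit(panel, table, cfg, mcmc):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return db.run_chains(panel, table, cfg, mcmc)


def _chainset(draws: dict, labels=("c", "m", "i")):
    any_arr = next(iter(draws.values()))
    return ChainSet(
        draws={k: np.asarray(v) for k, v in draws.items()},
        seeds=[0] * np.asarray(any_arr).shape[0],
        warmup=0,
        samples=np.asarray(any_arr).shape[1],
        thin=1,
        labels=labels,
        design_columns=["intercept"],
    )


class TestRunChains:
    def test_same_seed_gives_identical_draws(self, rng):
        n = 25
        table = _empty_table(n)
        beta = np.array([[-0.5, 0.3, 0.0]])
        X = np.ones((n, 1))
        panel = db.generate_outcomes(beta, np.eye(3), 0.0, X, 11)
        cfg = ModelConfig(gvs=False, include_random_effect=False, imputation=False)
        mcmc = McmcConfig(n_chains=2, warmup=80, samples=60, seed=7,
                          check_convergence=False)
        a = _fit(panel, table, cfg, mcmc)
        b = _fit(panel, table, cfg, mcmc)
        for name in a.param_names:
            np.testing.assert_array_equal(a.draws[name], b.draws[name])

    def test_intercept_only_posterior_tracks_sample_prevalence(self):
        # the latent scale is only weakly identified, so compare on the
        # probability scale: the model-implied marginal prevalence
        # E[expit(beta0 + tau*u)] must match the simulated prevalence
        n = 400
        table = _empty_table(n)
        beta = np.array([[-1.0, 0.0, 0.6]])
        X = np.ones((n, 1))
        panel = db.generate_outcomes(beta, 0.01 * np.eye(3), 0.0, X, 3)
        cfg = ModelConfig(gvs=False, include_random_effect=False, imputation=False)
        chains = _fit(
            panel, table, cfg,
            McmcConfig(n_chains=2, warmup=600, samples=600, seed=1,
                       check_convergence=False),
        )
        b0 = chains.pooled("beta")[:, 0, :]  # (draws, 3)
        tau = chains.pooled("tau")
        nodes, weights = np.polynomial.hermite_e.hermegauss(41)
        weights = weights / weights.sum()
        implied = np.einsum(
            "q,sjq->sj", weights,
            expit(b0[:, :, None] + tau[:, :, None] * nodes[None, None, :]),
        ).mean(axis=0)
        prev = panel.y.mean(axis=0)
        np.testing.assert_allclose(implied, prev, atol=0.05)

    def test_component_mismatch_raises(self):
        y = np.zeros((3, 4))
        panel = db.DefectPanel(
            [0, 1, 2], y, np.ones_like(y, dtype=bool), "defects",
            ("EH", "OP", "PEB", "DC"),
        )
        cfg = ModelConfig(axis_kind="regions", gvs=False, imputation=False)
        with pytest.raises(ValueError, match="components"):
            db.run_chains(panel, _empty_table(3), cfg, McmcConfig(n_chains=1))

    def test_registry_covers_all_parameter_blocks(self):
        n = 20
        rng = np.random.default_rng(0)
        x = rng.standard_normal((n, 2))
        table = PredictorTable(
            x, ["a", "b"],
            [ColumnMeta("a", "continuous"), ColumnMeta("b", "continuous")],
            np.ones_like(x, dtype=bool),
        )
        X = np.column_stack([np.ones(n), x])
        panel = db.generate_outcomes(np.zeros((3, 3)), np.eye(3), 0.0, X, 0)
        cfg = ModelConfig(gvs=True, include_random_effect=True, imputation=False)
        chains = _fit(panel, table, cfg,
                      McmcConfig(n_chains=2, warmup=50, samples=40,
                                 check_convergence=False))
        assert {"beta", "indicator", "psi", "b", "sigma2_b", "sigma2_beta",
                "tau", "omega"} <= set(chains.param_names)
        assert chains.draws["beta"].shape == (2, 40, 3, 3)


@pytest.fixture(scope="module")
def prior_chains():
    # all outcomes masked: the sampler must reproduce its priors
    n = 25
    y = np.zeros((n, 3))
    panel = db.DefectPanel(
        list(range(n)), y, np.zeros_like(y, dtype=bool), "regions",
        ("cervical", "middle", "incisal"),
    )
    rng = np.random.default_rng(2)
    x = rng.standard_normal((n, 2))
    table = PredictorTable(
        x, ["a", "b"],
        [ColumnMeta("a", "continuous"), ColumnMeta("b", "continuous")],
        np.ones_like(x, dtype=bool),
    )
    cfg = ModelConfig(gvs=True, include_random_effect=False, imputation=False)
    return _fit(
        panel, table, cfg,
        McmcConfig(n_chains=2, warmup=800, samples=1500, seed=4,
                   check_convergence=False),
    )


class TestPriorRecovery:
    def test_inclusion_probability_matches_beta_half_prior_mean(self, prior_chains):
        psi_hat = prior_chains.pooled("indicator").mean()
        assert psi_hat == pytest.approx(0.5, abs=0.05)

    def test_tau_matches_half_cauchy_prior_quartiles(self, prior_chains):
        draws = prior_chains.pooled("tau").ravel()
        expected = stats.halfcauchy.ppf([0.25, 0.5, 0.75], scale=2.5)
        observed = np.quantile(draws, [0.25, 0.5, 0.75])
        # MCMC draws are autocorrelated; compare quartiles with wide bands
        np.testing.assert_allclose(observed, expected, rtol=0.30)


class TestGelmanRubin:
    def test_identical_well_mixed_chains_give_unity(self):
        rng = np.random.default_rng(8)
        draws = np.tile(rng.normal(size=1000), (2, 1))
        cs = _chainset({"theta": draws})
        assert db.gelman_rubin(cs)["theta"] == pytest.approx(1.0, abs=0.01)

    def test_separated_chains_flagged(self):
        # two chains N(0,1) vs N(10,1): PSRF formula gives a huge value
        rng = np.random.default_rng(0)
        draws = np.stack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        cs = _chainset({"theta": draws})
        rhat = db.gelman_rubin(cs)["theta"]
        # independent oracle: plug the sample moments into the PSRF formula
        half = draws.reshape(4, 500)
        W = half.var(axis=1, ddof=1).mean()
        B = 500 * half.mean(axis=1).var(ddof=1)
        expected = np.sqrt((499 / 500 * W + B / 500) / W)
        assert rhat == pytest.approx(expected, rel=1e-10)
        assert rhat > 1.1

    def test_constant_parameter_reported_as_degenerate_unity(self):
        draws = np.ones((2, 100))
        cs = _chainset({"always_in": draws})
        rhat = db.gelman_rubin(cs)
        assert rhat["always_in"] == 1.0
        assert "always_in" in cs.meta.get("degenerate_parameters", [])

    def test_single_chain_warns_and_uses_split_halves(self):
        rng = np.random.default_rng(1)
        cs = _chainset({"theta": rng.normal(size=(1, 400))})
        with pytest.warns(UserWarning, match="split"):
            rhat = db.gelman_rubin(cs)
        assert rhat["theta"] < 1.1

    def test_agrees_with_arviz_rank_free_diagnostic(self):
        # arviz (split R-hat, rank-normalized) is an independent
        # implementation; on well-behaved Gaussian chains both should be
        # close to 1 and to each other
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(5)
        draws = rng.normal(size=(4, 500))
        ours = db.gelman_rubin(_chainset({"theta": draws}))["theta"]
        theirs = float(
            np.asarray(
                arviz.rhat(arviz.convert_to_dataset(draws[..., None])).to_array()
            ).squeeze()
        )
        assert ours == pytest.approx(theirs, abs=0.02)


class TestSummarize:
    def test_constant_draws_on_odds_scale(self):
        draws = np.full((2, 50, 1, 1), np.log(2.0))
        cs = _chainset({"beta": draws})
        cs.design_columns = ["intercept"]
        cs.labels = ("c",)
        out = db.summarize(cs, odds_scale=True, params=["beta"])
        row = out.iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert (row["q2.5"], row["q97.5"]) == (pytest.approx(2.0), pytest.approx(2.0))

    def test_odds_scale_reproduces_published_pattern(self):
        # log-odds mean -0.248, SD 0.104 -> odds 0.78 (geometric SD 1.11),
        # equal-tailed interval ~ (0.63, 0.95)
        rng = np.random.default_rng(0)
        raw = rng.standard_normal(20_000)
        raw = (raw - raw.mean()) / raw.std(ddof=1)
        draws = (-0.248 + 0.104 * raw).reshape(2, 10_000, 1, 1)
        cs = _chainset({"beta": draws})
        cs.design_columns = ["gestational_age"]
        cs.labels = ("incisal",)
        row = db.summarize(cs, odds_scale=True, params=["beta"]).iloc[0]
        assert row["mean"] == pytest.approx(0.78, abs=0.005)
        assert row["sd"] == pytest.approx(1.11, abs=0.005)
        assert row["q2.5"] == pytest.approx(0.63, abs=0.01)
        assert row["q97.5"] == pytest.approx(0.95, abs=0.01)

    def test_symmetric_draws_give_null_odds(self):
        draws = np.concatenate([np.linspace(-2, 2, 500)] * 2).reshape(2, 500, 1, 1)
        cs = _chainset({"beta": draws})
        cs.design_columns = ["x"]
        cs.labels = ("c",)
        row = db.summarize(cs, odds_scale=True, params=["beta"]).iloc[0]
        assert row["mean"] == pytest.approx(1.0)

    def test_invariant_to_chain_concatenation_order(self, rng):
        draws = rng.standard_normal((3, 200))
        a = _chainset({"sigma2_beta": draws})
        b = _chainset({"sigma2_beta": draws[::-1]})
        pd_a = db.summarize(a, params=["sigma2_beta"])
        pd_b = db.summarize(b, params=["sigma2_beta"])
        np.testing.assert_allclose(pd_a.to_numpy(), pd_b.to_numpy())


class TestCorrelationSummary:
    def test_identity_draws_zero_width_both_conventions(self):
        draws = np.tile(np.eye(3), (2, 40, 1, 1))
        cs = _chainset({"omega": draws})
        for conv in ("full_matrix", "cholesky_columns"):
            out = db.correlation_summary(cs, conv)
            np.testing.assert_allclose(out["mean"].to_numpy(), np.eye(3), atol=1e-12)
            np.testing.assert_allclose(
                out["q2.5"].to_numpy(), out["q97.5"].to_numpy(), atol=1e-12
            )

    def test_two_by_two_cholesky_row(self):
        omega = np.array([[1.0, 0.6], [0.6, 1.0]])
        draws = np.tile(omega, (2, 30, 1, 1))
        cs = _chainset({"omega": draws}, labels=("EH", "OP"))
        out = db.correlation_summary(cs, "cholesky_columns")
        np.testing.assert_allclose(out["mean"].loc["OP"].to_numpy(), [0.6, 0.8])
        assert out["mean"].loc["EH", "OP"] == 0.0  # upper triangle exactly zero

    def test_first_cholesky_column_equals_first_omega_column_mean(self, rng):
        draws = np.stack(
            [db.sample_lkj(3, 1.0, rng) for _ in range(60)]
        ).reshape(1, 60, 3, 3)
        cs = _chainset({"omega": draws})
        chol = db.correlation_summary(cs, "cholesky_columns")["mean"].to_numpy()
        full = db.correlation_summary(cs, "full_matrix")["mean"].to_numpy()
        np.testing.assert_allclose(chol[:, 0], full[:, 0], atol=1e-12)

    def test_unknown_convention_rejected(self):
        cs = _chainset({"omega": np.tile(np.eye(3), (1, 4, 1, 1))})
        with pytest.raises(ValueError):
            db.correlation_summary(cs, "nope")
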