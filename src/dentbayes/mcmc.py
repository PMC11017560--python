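"""MCMC engine: Metropolis-within-Gibbs sampler, diagnostics, summaries.

The sampler exploits the latent-Gaussian structure of the model:

* latent logits ``z``: column-wise updates — exact Gaussian conditional
  draws at masked outcome cells, random-walk Metropolis at observed cells
  (step sizes adapted during warmup only);
* coefficients ``beta``: exact multivariate-Gaussian conditional given the
  latents (the regression of z on X is linear with MVN errors), jointly
  over all indicator-active entries; inactive entries are refreshed from
  their N(0, sigma2_beta) prior (Kuo-Mallick);
* inclusion indicators: exact discrete Gibbs, one (predictor, component)
  cell at a time, with conjugate Beta updates for psi;
* random intercepts ``b``: exact Gaussian conditionals;
* variances sigma2_beta, sigma2_b and the scales tau: scalar
  log-random-walk Metropolis;
* the correlation matrix Omega: scalar Metropolis on atanh canonical
  partial correlations with the LKJ-implied scaled-Beta priors (the C-vine
  parameterization, exactly equivalent to LKJ(eta));
* missing predictor cells: exact conditionals (Gaussian for continuous,
  two- or three-point discrete for binary/categorical), with their
  hyperparameters updated conjugately or by scalar Metropolis.

Any correct sampler satisfies the module contract; correctness is
established by prior-recovery and parameter-recovery properties in the
test suite, not by matching a particular sampler's trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import DefectPanel, PredictorTable
from .imputation import build_imputation_models, categorical_probabilities
from .model import (
    HyperPriorConfig,
    ModelConfig,
    cpc_beta_shapes,
    cpc_to_cholesky,
    expit,
    gamma_logpdf,
    halfcauchy_logpdf,
    log1pexp,
)

__all__ = [
    "McmcConfig",
    "PAPER_SCALE",
    "ChainSet",
    "run_chains",
    "gelman_rubin",
    "summarize",
    "correlation_summary",
    "build_design",
]


@dataclass
class McmcConfig:
    """Chain layout.  Desk-scale defaults; ``PAPER_SCALE`` mirrors the
    published runs (2,000 samples after a 400,000-iteration burn-in)."""

    n_chains: int = 4
    warmup: int = 1000
    samples: int = 1000
    thin: int = 1
    seed: int = 0
    record_z: bool = False
    rhat_threshold: float = 1.05
    check_convergence: bool = True


PAPER_SCALE = McmcConfig(n_chains=4, warmup=400_000, samples=2000)


@dataclass
class ChainSet:
    """Posterior draws per parameter per chain, plus run metadata.

    ``draws[name]`` has shape (n_chains, n_draws, *param_shape); every
    registered parameter is present in every chain and all chains have
    equal length.
    """

    draws: dict[str, np.ndarray]
    seeds: list[int]
    warmup: int
    samples: int
    thin: int
    labels: tuple[str, ...]
    design_columns: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {v.shape[:2] for v in self.draws.values()}
        if len(lengths) > 1:
            raise ValueError("all parameters must have equal chain x draw shape")

    @property
    def param_names(self) -> list[str]:
        return list(self.draws)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """All post-warmup draws of one parameter, chains concatenated."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])


def build_design(table: PredictorTable) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Design matrix with leading intercept column, its names, and mask."""
    n = table.n_subjects
    X = np.column_stack([np.ones(n), table.x])
    mask = np.column_stack([np.ones(n, dtype=bool), table.observed_mask])
    return X, ["intercept", *table.colnames], mask


# ---------------------------------------------------------------------------
# sampler internals


class _State:
    """Mutable per-chain sampler state with residual bookkeeping."""

    def __init__(self, panel, X, xmask, cfg: ModelConfig, rng):
        self.rng = rng
        self.n, self.d = panel.y.shape
        self.p1 = X.shape[1]
        self.y = panel.y
        self.obs = panel.observed_mask
        self.X = X.copy()
        self.xmask = xmask
        h = cfg.hyper
        self.h = h
        self.cfg = cfg
        self.z = np.where(self.obs, 2.0 * panel.y - 1.0, 0.0) + 0.1 * rng.standard_normal(
            (self.n, self.d)
        )
        self.beta = 0.01 * rng.standard_normal((self.p1, self.d))
        self.sigma2_beta = 2.0
        self.b = np.zeros(self.n) if cfg.include_random_effect else None
        self.sigma2_b = 1.0
        self.tau = np.ones(self.d)
        self.zc = np.zeros((self.d, self.d))  # canonical partial correlations
        self.cpc_shapes = cpc_beta_shapes(self.d, h.eta)
        if cfg.gvs and self.p1 > 1:
            self.indicator = (rng.random((self.p1 - 1, self.d)) < 0.5).astype(float)
            self.psi = np.full((self.p1 - 1, self.d), 0.5)
        else:
            self.indicator = None
            self.psi = None
        self.step_z = np.full(self.d, 0.8)
        self.acc_z = np.zeros(self.d)
        self.try_z = np.zeros(self.d)
        self.step_scalar = {}
        self._refresh_cov()
        self._refresh_mean()

    # -- covariance helpers ------------------------------------------------
    def _refresh_cov(self):
        L = cpc_to_cholesky(self.zc)
        self.omega = L @ L.T
        np.fill_diagonal(self.omega, 1.0)
        self.sigma = self.tau[:, None] * self.omega * self.tau[None, :]
        Ls = np.linalg.cholesky(self.sigma)
        inv = np.linalg.inv(Ls)
        self.W = inv.T @ inv
        self.logdet = 2.0 * np.sum(np.log(np.diag(Ls)))

    def _xi(self):
        xi = self.beta.copy()
        if self.indicator is not None:
            xi[1:] *= self.indicator
        return xi

    def _refresh_mean(self):
        self.xi = self._xi()
        self.mu = self.X @ self.xi
        if self.b is not None:
            self.mu += self.b[:, None]
        self.E = self.z - self.mu

    def mvn_quad(self, E=None):
        E = self.E if E is None else E
        return float(np.sum((E @ self.W) * E))

    def mvn_loglik(self, E=None):
        return -0.5 * (self.n * self.logdet + self.mvn_quad(E))

    # -- update blocks -----------------------------------------------------
    def update_z(self, adapt=False, adapt_rate=0.05):
        for j in range(self.d):
            G = self.E @ self.W
            wjj = self.W[j, j]
            cond_mean = self.z[:, j] - G[:, j] / wjj
            cond_sd = 1.0 / np.sqrt(wjj)
            masked = ~self.obs[:, j]
            if masked.any():
                self.z[masked, j] = cond_mean[masked] + cond_sd * self.rng.standard_normal(
                    masked.sum()
                )
            obs = self.obs[:, j]
            if obs.any():
                cur = self.z[obs, j]
                prop = cur + self.step_z[j] * self.rng.standard_normal(obs.sum())
                yj = self.y[obs, j]
                m = cond_mean[obs]
                dlog = (
                    yj * (prop - cur)
                    - log1pexp(prop)
                    + log1pexp(cur)
                    - 0.5 * wjj * ((prop - m) ** 2 - (cur - m) ** 2)
                )
                acc = np.log(self.rng.random(obs.sum())) < dlog
                cur[acc] = prop[acc]
                self.z[obs, j] = cur
                self.try_z[j] += 1
                rate = acc.mean() if acc.size else 0.0
                self.acc_z[j] += rate
                if adapt:
                    self.step_z[j] *= np.exp(adapt_rate * (rate - 0.44))
            self.E[:, j] = self.z[:, j] - self.mu[:, j]

    def update_b(self):
        if self.b is None:
            return
        wsum = self.W.sum()
        wrow = self.W.sum(axis=0)
        resid = self.z - self.X @ self.xi  # excludes b
        prec = wsum + 1.0 / self.sigma2_b
        mean = (resid @ wrow) / prec
        self.b = mean + self.rng.standard_normal(self.n) / np.sqrt(prec)
        self._refresh_mean()

    def update_beta(self):
        r = self.z - (self.b[:, None] if self.b is not None else 0.0)
        active = np.ones((self.p1, self.d), dtype=bool)
        if self.indicator is not None:
            active[1:] = self.indicator.astype(bool)
        pa, ja = np.nonzero(active)
        G = self.X.T @ self.X
        P = G[pa[:, None], pa[None, :]] * self.W[ja[:, None], ja[None, :]]
        P[np.diag_indices_from(P)] += 1.0 / self.sigma2_beta
        H = self.X.T @ (r @ self.W)
        hvec = H[pa, ja]
        Lp = np.linalg.cholesky(P)
        mean = np.linalg.solve(Lp.T, np.linalg.solve(Lp, hvec))
        draw = mean + np.linalg.solve(Lp.T, self.rng.standard_normal(len(hvec)))
        new = self.rng.normal(0.0, np.sqrt(self.sigma2_beta), size=(self.p1, self.d))
        new[pa, ja] = draw
        self.beta = new
        self._refresh_mean()

    def update_indicators(self):
        if self.indicator is None:
            return
        G = self.E @ self.W
        order = self.rng.permutation((self.p1 - 1) * self.d)
        for flat in order:
            p, j = divmod(int(flat), self.d)
            xcol = self.X[:, p + 1]
            c = self.beta[p + 1, j] * xcol
            cur = self.indicator[p, j]
            gb = G[:, j] + cur * c * self.W[j, j]
            dlik = float(c @ gb) - 0.5 * self.W[j, j] * float(c @ c)
            dprior = np.log(self.psi[p, j]) - np.log1p(-self.psi[p, j])
            pnew = expit(dlik + dprior)
            new = float(self.rng.random() < pnew)
            if new != cur:
                delta = -(new - cur) * c  # residual change in column j
                self.E[:, j] += delta
                G += delta[:, None] * self.W[j, :][None, :]
                self.indicator[p, j] = new
        self.psi = self.rng.beta(
            self.h.psi_a + self.indicator, self.h.psi_b + 1.0 - self.indicator
        )
        self._refresh_mean()

    def _scalar_mh(self, key, value, logtarget, step=0.3, adapt=False):
        cur_lp = logtarget(value)
        stp = self.step_scalar.get(key, step)
        prop = value + stp * self.rng.standard_normal()
        new_lp = logtarget(prop)
        accept = np.log(self.rng.random()) < new_lp - cur_lp
        if adapt:
            self.step_scalar[key] = stp * np.exp(0.05 * ((1.0 if accept else 0.0) - 0.3))
        return (prop, new_lp) if accept else (value, cur_lp)

    def update_variances(self, adapt=False):
        nb = self.beta.size

        def lp_s2beta(u):
            s2 = np.exp(u)
            ss = float(np.sum(self.beta**2))
            return (
                -0.5 * nb * (np.log(2 * np.pi) + u)
                - 0.5 * ss / s2
                + gamma_logpdf(s2, self.h.beta_var_shape, self.h.beta_var_rate)
                + u
            )

        u, _ = self._scalar_mh("s2beta", np.log(self.sigma2_beta), lp_s2beta, adapt=adapt)
        self.sigma2_beta = float(np.exp(u))

        if self.b is not None:

            def lp_s2b(u):
                s2 = np.exp(u)
                ss = float(np.sum(self.b**2))
                return (
                    -0.5 * self.n * (np.log(2 * np.pi) + u)
                    - 0.5 * ss / s2
                    + gamma_logpdf(s2, self.h.b_var_shape, self.h.b_var_rate)
                    + u
                )

            u, _ = self._scalar_mh("s2b", np.log(self.sigma2_b), lp_s2b, adapt=adapt)
            self.sigma2_b = float(np.exp(u))

    def update_covariance(self, adapt=False):
        # scales tau_j, log-random-walk (centered: latents fixed)
        for j in range(self.d):

            def lp_tau(u, j=j):
                tau = self.tau.copy()
                tau[j] = np.exp(u)
                return self._cov_loglik(tau, self.zc) + halfcauchy_logpdf(
                    np.exp(u), self.h.tau_scale
                ) + u

            u, _ = self._scalar_mh(f"tau{j}", np.log(self.tau[j]), lp_tau, adapt=adapt)
            self.tau[j] = np.exp(u)
        self._refresh_cov()
        self._interweave_tau(adapt=adapt)
        self._interweave_cpc(adapt=adapt)
        # canonical partial correlations, atanh-random-walk
        for i in range(1, self.d):
            for j in range(i):
                shape = self.cpc_shapes[j]

                def lp_cpc(y, i=i, j=j, shape=shape):
                    zc = self.zc.copy()
                    zc[i, j] = np.tanh(y)
                    lj = np.log1p(-np.tanh(y) ** 2)  # tanh Jacobian
                    return (
                        self._cov_loglik(self.tau, zc)
                        + (shape - 1.0) * np.log1p(-np.tanh(y) ** 2)
                        + lj
                    )

                y, _ = self._scalar_mh(
                    f"cpc{i}{j}", np.arctanh(self.zc[i, j]), lp_cpc, adapt=adapt
                )
                self.zc[i, j] = np.tanh(y)
        self._refresh_cov()

    def update_scale_group(self, adapt=False):
        """Group-scale move: multiply (z_j, beta_.j, tau_j) by a common
        factor.  The likelihood is nearly flat along this direction (the
        latent-logit scale ridge), so single-site updates random-walk very
        slowly across it; the group move traverses it in one step.  The
        Jacobian of the scaling is c^(n + p + 2) per component."""
        for j in range(self.d):
            stp = self.step_scalar.get(f"grp{j}", 0.15)
            u = stp * self.rng.standard_normal()
            c = np.exp(u)
            obs = self.obs[:, j]
            z_new = c * self.z[:, j]
            beta_new = self.beta.copy()
            beta_new[:, j] *= c
            tau_new = self.tau.copy()
            tau_new[j] *= c
            xi_new = beta_new.copy()
            if self.indicator is not None:
                xi_new[1:] *= self.indicator
            mu_new = self.X @ xi_new
            if self.b is not None:
                mu_new += self.b[:, None]
            E_new = self.E.copy()
            E_new[:, j] = z_new - mu_new[:, j]
            # component terms that change: Bernoulli in column j, full MVN
            # quad/logdet, beta prior in column j, tau prior, Jacobian
            sigma_new = tau_new[:, None] * self.omega * tau_new[None, :]
            Ls = np.linalg.cholesky(sigma_new)
            sol = np.linalg.solve(Ls, E_new.T)
            quad_new = float(np.sum(sol**2))
            logdet_new = 2.0 * np.sum(np.log(np.diag(Ls)))
            dlog = (
                float(
                    np.sum(
                        self.y[obs, j] * (z_new[obs] - self.z[obs, j])
                        - log1pexp(z_new[obs])
                        + log1pexp(self.z[obs, j])
                    )
                )
                - 0.5 * (self.n * logdet_new + quad_new)
                + 0.5 * (self.n * self.logdet + self.mvn_quad())
                - 0.5 * float(np.sum(beta_new[:, j] ** 2 - self.beta[:, j] ** 2))
                / self.sigma2_beta
                + halfcauchy_logpdf(tau_new[j], self.h.tau_scale)
                - halfcauchy_logpdf(self.tau[j], self.h.tau_scale)
                + (self.n + self.p1 + 1) * u
            )
            accept = np.log(self.rng.random()) < dlog
            if accept:
                self.z[:, j] = z_new
                self.beta = beta_new
                self.tau = tau_new
                self._refresh_cov()
                self._refresh_mean()
            if adapt:
                self.step_scalar[f"grp{j}"] = stp * np.exp(
                    0.05 * ((1.0 if accept else 0.0) - 0.3)
                )

    def _interweave_tau(self, adapt=False):
        """Non-centered rescaling move: hold u = (z - mu)/tau fixed and move
        tau_j together with its latent column.  In this parameterization the
        Bernoulli likelihood informs tau_j directly, which breaks the slow
        random-walk coupling between the scales and the latent logits."""
        for j in range(self.d):
            uj = self.E[:, j] / self.tau[j]
            obs = self.obs[:, j]
            cur_z = self.z[obs, j]
            yj = self.y[obs, j]
            stp = self.step_scalar.get(f"itau{j}", 0.3)
            lt_new = np.log(self.tau[j]) + stp * self.rng.standard_normal()
            tau_new = np.exp(lt_new)
            new_z = self.mu[obs, j] + tau_new * uj[obs]
            dlog = (
                float(np.sum(yj * (new_z - cur_z) - log1pexp(new_z) + log1pexp(cur_z)))
                + halfcauchy_logpdf(tau_new, self.h.tau_scale)
                - halfcauchy_logpdf(self.tau[j], self.h.tau_scale)
                + (lt_new - np.log(self.tau[j]))
            )
            accept = np.log(self.rng.random()) < dlog
            if accept:
                self.tau[j] = tau_new
                self.z[:, j] = self.mu[:, j] + tau_new * uj
                self.E[:, j] = self.z[:, j] - self.mu[:, j]
            if adapt:
                self.step_scalar[f"itau{j}"] = stp * np.exp(
                    0.05 * ((1.0 if accept else 0.0) - 0.3)
                )
        self._refresh_cov()

    def _interweave_cpc(self, adapt=False):
        """Non-centered correlation move: hold the whitened residuals
        w = L^-1 D^-1 (z - mu) fixed and move one canonical partial
        correlation together with the latent logits z = mu + D L' w.
        In these coordinates the Bernoulli data inform Omega directly;
        the n * sum(log L_jj) term is the z -> w Jacobian."""
        L = cpc_to_cholesky(self.zc)
        # w = L^-1 (E / tau), per subject
        w = np.linalg.solve(L, (self.E / self.tau[None, :]).T).T  # (n, d)
        for i in range(1, self.d):
            for j in range(i):
                shape = self.cpc_shapes[j]
                cur_y = np.arctanh(self.zc[i, j])
                stp = self.step_scalar.get(f"icpc{i}{j}", 0.2)
                new_y = cur_y + stp * self.rng.standard_normal()
                zc_new = self.zc.copy()
                zc_new[i, j] = np.tanh(new_y)
                try:
                    L_new = cpc_to_cholesky(zc_new)
                except ValueError:
                    continue
                z_new = self.mu + (w @ L_new.T) * self.tau[None, :]
                obs = self.obs
                dbern = float(
                    np.sum(
                        self.y[obs] * (z_new[obs] - self.z[obs])
                        - log1pexp(z_new[obs])
                        + log1pexp(self.z[obs])
                    )
                )
                dprior = shape * (
                    np.log1p(-np.tanh(new_y) ** 2) - np.log1p(-np.tanh(cur_y) ** 2)
                )
                djac = self.n * float(
                    np.sum(np.log(np.diag(L_new)) - np.log(np.diag(L)))
                )
                accept = np.log(self.rng.random()) < dbern + dprior + djac
                if accept:
                    self.zc = zc_new
                    L = L_new
                    self.z = z_new
                    self.E = self.z - self.mu
                if adapt:
                    self.step_scalar[f"icpc{i}{j}"] = stp * np.exp(
                        0.05 * ((1.0 if accept else 0.0) - 0.3)
                    )
        self._refresh_cov()

    def _cov_loglik(self, tau, zc):
        """MVN(z | mu, Sigma(tau, zc)) log-likelihood up to a constant."""
        L = cpc_to_cholesky(zc)
        omega = L @ L.T
        np.fill_diagonal(omega, 1.0)
        sigma = tau[:, None] * omega * tau[None, :]
        try:
            Ls = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return -np.inf
        sol = np.linalg.solve(Ls, self.E.T)
        quad = float(np.sum(sol**2))
        logdet = 2.0 * np.sum(np.log(np.diag(Ls)))
        return -0.5 * (self.n * logdet + quad)


class _Imputer:
    """Missing-predictor state living alongside a :class:`_State`."""

    def __init__(self, state: _State, table: PredictorTable, rng):
        self.state = state
        self.table = table
        self.rng = rng
        models = build_imputation_models(table)
        self.continuous = []
        for prior in models["continuous"]:
            q = table.colnames.index(prior.column)
            rows = np.nonzero(~table.observed_mask[:, q])[0]
            self.continuous.append(
                {"prior": prior, "col": q, "rows": rows, "sigma2": 1.0}
            )
            state.X[rows, q + 1] = prior.mean
        self.binary = []
        for prior in models["binary"]:
            q = table.colnames.index(prior.column)
            rows = np.nonzero(~table.observed_mask[:, q])[0]
            rate = prior.posterior_mean_nu()
            state.X[rows, q + 1] = (rng.random(len(rows)) < rate).astype(float)
            self.binary.append({"prior": prior, "col": q, "rows": rows, "nu": rate})
        self.categorical = []
        for cmodel in models["categorical"]:
            cols = table.columns_for(cmodel.column)
            rows = np.nonzero(~table.observed_mask[:, cols[0]])[0]
            obs_rows = np.nonzero(table.observed_mask[:, cols[0]])[0]
            # categories: 0 = reference (both dummies 0), 1, 2
            cats = np.zeros(table.n_subjects, dtype=int)
            cats[table.x[:, cols[0]] == 1] = 1
            cats[table.x[:, cols[1]] == 1] = 2
            freqs = np.bincount(cats[obs_rows], minlength=3) + 1.0
            freqs /= freqs.sum()
            cats[rows] = rng.choice(3, size=len(rows), p=freqs)
            race_d, race_missing, race_freqs = self._race_dummies(cmodel)
            for r in rows:
                state.X[r, cols[0] + 1] = float(cats[r] == 1)
                state.X[r, cols[1] + 1] = float(cats[r] == 2)
            self.categorical.append(
                {
                    "model": cmodel,
                    "cols": cols,
                    "rows": rows,
                    "cats": cats,
                    "race_dummies": race_d,
                    "race_missing": race_missing,
                    "race_freqs": race_freqs,
                    "sigma2_zeta": 1.0,
                }
            )
        state._refresh_mean()

    def _race_dummies(self, cmodel):
        """Dummy-code maternal race; missing race drawn from empirical
        frequencies at init and resampled each sweep."""
        table = self.table
        n = table.n_subjects
        if table.race is None or not table.race_levels:
            return np.zeros((n, cmodel.zeta1.shape[0])), np.zeros(0, dtype=int), None
        levels = table.race_levels
        k = len(levels) - 1
        dummies = np.zeros((n, max(k, 1)))
        known = np.array([r is not None for r in table.race])
        freqs = np.bincount(
            [levels.index(r) for r in table.race[known]], minlength=len(levels)
        ) + 1.0
        freqs = freqs / freqs.sum()
        for i, r in enumerate(table.race):
            lev = levels.index(r) if r is not None else int(
                self.rng.choice(len(levels), p=freqs)
            )
            for kk in range(1, len(levels)):
                dummies[i, kk - 1] = float(lev == kk)
        return dummies, np.nonzero(~known)[0], freqs

    @property
    def missing_names(self) -> list[str]:
        names = []
        for c in self.continuous:
            names += [f"x[{self.table.colnames[c['col']]},{r}]" for r in c["rows"]]
        for c in self.binary:
            names += [f"x[{self.table.colnames[c['col']]},{r}]" for r in c["rows"]]
        for c in self.categorical:
            names += [f"x[{c['model'].column},{r}]" for r in c["rows"]]
        return names

    def missing_values(self) -> np.ndarray:
        vals = []
        for c in self.continuous:
            vals.append(self.state.X[c["rows"], c["col"] + 1])
        for c in self.binary:
            vals.append(self.state.X[c["rows"], c["col"] + 1])
        for c in self.categorical:
            vals.append(c["cats"][c["rows"]].astype(float))
        return np.concatenate(vals) if vals else np.zeros(0)

    def update(self, adapt=False):
        s = self.state
        for c in self.continuous:
            rows, q = c["rows"], c["col"]
            if len(rows) == 0:
                continue
            xi_row = s.xi[q + 1]
            a = float(xi_row @ s.W @ xi_row)
            cur = s.X[rows, q + 1]
            C = s.E[rows] + cur[:, None] * xi_row  # residual at x=0
            wxi = s.W @ xi_row
            prec = a + 1.0 / c["sigma2"]
            mean = (C @ wxi + c["prior"].mean / c["sigma2"]) / prec
            new = mean + self.rng.standard_normal(len(rows)) / np.sqrt(prec)
            s.X[rows, q + 1] = new
            s.E[rows] -= (new - cur)[:, None] * xi_row
            s.mu[rows] += (new - cur)[:, None] * xi_row
            # column variance: scalar MH on log scale, all cells
            resid2 = float(np.sum((s.X[:, q + 1] - c["prior"].mean) ** 2))
            nn = s.n

            def lp(u, resid2=resid2, nn=nn, pr=c["prior"]):
                s2 = np.exp(u)
                return (
                    -0.5 * nn * (np.log(2 * np.pi) + u)
                    - 0.5 * resid2 / s2
                    + gamma_logpdf(s2, pr.var_shape, pr.var_rate)
                    + u
                )

            u, _ = s._scalar_mh(f"imp_s2_{q}", np.log(c["sigma2"]), lp, adapt=adapt)
            c["sigma2"] = float(np.exp(u))
        for c in self.binary:
            rows, q = c["rows"], c["col"]
            if len(rows) == 0:
                continue
            xi_row = s.xi[q + 1]
            a = float(xi_row @ s.W @ xi_row)
            cur = s.X[rows, q + 1]
            C = s.E[rows] + cur[:, None] * xi_row  # residual at x=0
            dlik = C @ (s.W @ xi_row) - 0.5 * a
            logit_nu = np.log(c["nu"]) - np.log1p(-c["nu"])
            pone = expit(dlik + logit_nu)
            new = (self.rng.random(len(rows)) < pone).astype(float)
            s.X[rows, q + 1] = new
            s.E[rows] -= (new - cur)[:, None] * xi_row
            s.mu[rows] += (new - cur)[:, None] * xi_row
            ones = float(np.sum(s.X[:, q + 1]))
            c["nu"] = float(self.rng.beta(1.0 + ones, 1.0 + s.n - ones))
        for c in self.categorical:
            self._update_categorical(c, adapt=adapt)

    def _update_categorical(self, c, adapt=False):
        s = self.state
        cols = c["cols"]
        model = c["model"]
        xi1 = s.xi[cols[0] + 1]
        xi2 = s.xi[cols[1] + 1]
        v_all = categorical_probabilities(c["race_dummies"], model.zeta0, model.zeta1)
        v_all = np.atleast_2d(v_all)
        for r in c["rows"]:
            cur_cat = c["cats"][r]
            d1c, d2c = float(cur_cat == 1), float(cur_cat == 2)
            base = s.E[r] + d1c * xi1 + d2c * xi2  # residual with both dummies 0
            logp = np.empty(3)
            for cat in range(3):
                e = base - float(cat == 1) * xi1 - float(cat == 2) * xi2
                logp[cat] = -0.5 * float(e @ s.W @ e) + np.log(v_all[r, cat])
            logp -= logp.max()
            prob = np.exp(logp)
            prob /= prob.sum()
            new_cat = int(self.rng.choice(3, p=prob))
            if new_cat != cur_cat:
                c["cats"][r] = new_cat
                s.X[r, cols[0] + 1] = float(new_cat == 1)
                s.X[r, cols[1] + 1] = float(new_cat == 2)
                delta = (float(new_cat == 1) - d1c) * xi1 + (float(new_cat == 2) - d2c) * xi2
                s.E[r] -= delta
                s.mu[r] += delta
        # missing maternal race: discrete conditional ~ freq(level) * v_cat
        if c["race_freqs"] is not None and len(c["race_missing"]):
            n_lev = len(c["race_freqs"])
            for r in c["race_missing"]:
                logp = np.empty(n_lev)
                for lev in range(n_lev):
                    dummy = np.zeros(model.zeta1.shape[0])
                    if lev >= 1:
                        dummy[lev - 1] = 1.0
                    v = categorical_probabilities(dummy, model.zeta0, model.zeta1)
                    logp[lev] = np.log(c["race_freqs"][lev]) + np.log(
                        v[c["cats"][r]]
                    )
                logp -= logp.max()
                prob = np.exp(logp)
                prob /= prob.sum()
                lev = int(self.rng.choice(n_lev, p=prob))
                c["race_dummies"][r] = 0.0
                if lev >= 1:
                    c["race_dummies"][r, lev - 1] = 1.0
        # multinomial-logit coefficients: scalar MH per free entry
        cats = c["cats"]
        race = c["race_dummies"]
        s2z = c["sigma2_zeta"]

        def loglik(zeta0, zeta1):
            v = np.atleast_2d(categorical_probabilities(race, zeta0, zeta1))
            return float(np.sum(np.log(v[np.arange(len(cats)), cats])))

        for label, arr, index in self._free_zeta(model):
            def lp(val, arr=arr, index=index):
                old = arr[index]
                arr[index] = val
                out = loglik(model.zeta0, model.zeta1) + stats.norm.logpdf(
                    val, scale=np.sqrt(s2z)
                )
                arr[index] = old
                return out

            val, _ = s._scalar_mh(f"zeta_{label}", arr[index], lp, adapt=adapt)
            arr[index] = val
        free = [arr[index] for _, arr, index in self._free_zeta(model)]
        ssz = float(np.sum(np.square(free)))
        nz = len(free)

        def lp_s2z(u):
            s2 = np.exp(u)
            return (
                -0.5 * nz * (np.log(2 * np.pi) + u)
                - 0.5 * ssz / s2
                + gamma_logpdf(s2, s.h.zeta_var_shape, s.h.zeta_var_rate)
                + u
            )

        u, _ = s._scalar_mh("s2zeta", np.log(s2z), lp_s2z, adapt=adapt)
        c["sigma2_zeta"] = float(np.exp(u))

    def _free_zeta(self, model):
        """Free coefficients: reference category 0 pinned at zero."""
        out = []
        for cat in (1, 2):
            out.append((f"0_{cat}", model.zeta0, cat))
        for k in range(model.zeta1.shape[0]):
            for cat in (1, 2):
                out.append((f"1_{k}_{cat}", model.zeta1, (k, cat)))
        return out


def _one_chain(panel, table, cfg: ModelConfig, mcmc: McmcConfig, seed: int):
    rng = np.random.default_rng(seed)
    X, design_cols, xmask = build_design(table)
    if not xmask.all() and not cfg.imputation:
        raise ValueError(
            "predictor table has missing cells but imputation is disabled"
        )
    state = _State(panel, X, xmask, cfg, rng)
    imputer = _Imputer(state, table, rng) if (cfg.imputation and not xmask.all()) else None
    n_iter = mcmc.warmup + mcmc.samples * mcmc.thin
    rec: dict[str, list] = {k: [] for k in _registry(state, imputer, mcmc)}
    for it in range(n_iter):
        adapt = it < mcmc.warmup
        state.update_z(adapt=adapt)
        state.update_b()
        state.update_beta()
        state.update_indicators()
        state.update_variances(adapt=adapt)
        state.update_covariance(adapt=adapt)
        state.update_scale_group(adapt=adapt)
        if imputer is not None:
            imputer.update(adapt=adapt)
        if it % 200 == 0 and not np.isfinite(state.E).all():
            raise FloatingPointError(
                f"divergent state at iteration {it}: non-finite residuals"
            )
        if it >= mcmc.warmup and (it - mcmc.warmup) % mcmc.thin == 0:
            _record(rec, state, imputer, mcmc)
    return {k: np.asarray(v) for k, v in rec.items()}


def _registry(state: _State, imputer, mcmc: McmcConfig) -> list[str]:
    names = ["beta", "sigma2_beta", "tau", "omega"]
    if state.indicator is not None:
        names += ["indicator", "psi"]
    if state.b is not None:
        names += ["b", "sigma2_b"]
    if imputer is not None and imputer.missing_names:
        names += ["x_missing"]
    if mcmc.record_z:
        names += ["z"]
    return names


def _record(rec, state: _State, imputer, mcmc: McmcConfig):
    rec["beta"].append(state.beta.copy())
    rec["sigma2_beta"].append(state.sigma2_beta)
    rec["tau"].append(state.tau.copy())
    rec["omega"].append(state.omega.copy())
    if "indicator" in rec:
        rec["indicator"].append(state.indicator.copy())
        rec["psi"].append(state.psi.copy())
    if "b" in rec:
        rec["b"].append(state.b.copy())
        rec["sigma2_b"].append(state.sigma2_b)
    if "x_missing" in rec:
        rec["x_missing"].append(imputer.missing_values())
    if "z" in rec:
        rec["z"].append(state.z.copy())


def run_chains(
    panel: DefectPanel,
    table: PredictorTable,
    config: ModelConfig | None = None,
    mcmc: McmcConfig | None = None,
) -> ChainSet:
    """Fit the configured model by MCMC; reproducible given the seed.

    Returns draws for every parameter including inclusion indicators and
    imputed predictor values.  Convergence is checked with the
    Gelman-Rubin diagnostic and a warning (never a silent pass) is issued
    and attached to the result when any continuous parameter exceeds the
    threshold.
    """
    config = config or ModelConfig()
    mcmc = mcmc or McmcConfig()
    if panel.n_components != config.n_components:
        raise ValueError(
            f"panel has {panel.n_components} components but config expects "
            f"{config.n_components}"
        )
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
             np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)]
    per_chain = [_one_chain(panel, table, config, mcmc, s) for s in seeds]
    draws = {
        k: np.stack([c[k] for c in per_chain]) for k in per_chain[0]
    }
    _, design_cols, _ = build_design(table)
    chains = ChainSet(
        draws=draws,
        seeds=seeds,
        warmup=mcmc.warmup,
        samples=mcmc.samples,
        thin=mcmc.thin,
        labels=panel.labels,
        design_columns=design_cols,
        meta={"model": config, "mcmc": mcmc},
    )
    if mcmc.check_convergence:
        rhat = gelman_rubin(chains)
        bad = {
            k: float(np.nanmax(v))
            for k, v in rhat.items()
            if k not in ("indicator",) and np.nanmax(v) > mcmc.rhat_threshold
        }
        chains.meta["rhat_max"] = {k: float(np.nanmax(v)) for k, v in rhat.items()}
        chains.meta["converged"] = not bad
        if bad:
            warnings.warn(
                f"Gelman-Rubin diagnostic above {mcmc.rhat_threshold} for: {bad}",
                stacklevel=2,
            )
    return chains


# ---------------------------------------------------------------------------
# diagnostics and summaries


def gelman_rubin(chains: ChainSet) -> dict[str, np.ndarray]:
    """Potential-scale-reduction statistic per parameter (split chains).

    Each chain is split in half, so the diagnostic is defined even for a
    single chain (with a warning).  A parameter with zero variance across
    all chains is degenerate and reported as exactly 1.
    """
    if chains.n_chains < 2:
        warnings.warn("single chain: using split-chain R-hat only", stacklevel=2)
    out = {}
    degenerate = []
    for name, arr in chains.draws.items():
        c, t = arr.shape[:2]
        half = t // 2
        if half < 2:
            raise ValueError("chains too short for the Gelman-Rubin diagnostic")
        halves = np.concatenate([arr[:, :half], arr[:, half : 2 * half]], axis=0)
        m, L = halves.shape[0], half
        flat = halves.reshape(m, L, -1)
        means = flat.mean(axis=1)  # (m, k)
        variances = flat.var(axis=1, ddof=1)
        Wv = variances.mean(axis=0)
        Bv = L * means.var(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            var_hat = (L - 1) / L * Wv + Bv / L
            rhat = np.sqrt(var_hat / Wv)
        zero = Wv <= 1e-300
        if zero.any():
            degenerate.append(name)
            rhat[zero] = 1.0
        shape = arr.shape[2:]
        out[name] = rhat.reshape(shape) if shape else float(rhat[0])
    out_meta = getattr(chains, "meta", None)
    if degenerate and isinstance(out_meta, dict):
        out_meta.setdefault("degenerate_parameters", degenerate)
    return out


def _flatten_names(name: str, shape: tuple, chains: ChainSet) -> list[str]:
    if not shape:
        return [name]
    if name in ("beta",):
        rows = chains.design_columns
        return [f"beta[{r},{c}]" for r in rows for c in chains.labels]
    if name in ("indicator", "psi"):
        rows = chains.design_columns[1:]
        return [f"{name}[{r},{c}]" for r in rows for c in chains.labels]
    if name == "tau":
        return [f"tau[{c}]" for c in chains.labels]
    if name == "omega":
        return [
            f"omega[{a},{b}]" for a in chains.labels for b in chains.labels
        ]
    total = int(np.prod(shape))
    return [f"{name}[{i}]" for i in range(total)]


def summarize(
    chains: ChainSet,
    odds_scale: bool = False,
    params: list[str] | None = None,
) -> pd.DataFrame:
    """Posterior mean, SD and equal-tailed 95% interval per scalar parameter.

    On the odds scale (for log-odds parameters such as ``beta``), the mean
    is the exponentiated log-odds mean, the SD is the geometric SD
    exp(SD of log-odds), and the interval endpoints are exponentiated —
    the convention of the published odds-scale tables.
    """
    rows = []
    for name in params or chains.param_names:
        arr = chains.pooled(name)
        flat = arr.reshape(arr.shape[0], -1)
        labels = _flatten_names(name, chains.draws[name].shape[2:], chains)
        mean = flat.mean(axis=0)
        sd = flat.std(axis=0, ddof=1) if flat.shape[0] > 1 else np.zeros(flat.shape[1])
        lo, hi = np.quantile(flat, [0.025, 0.975], axis=0)
        for k, lab in enumerate(labels):
            if odds_scale:
                rows.append(
                    {
                        "parameter": lab,
                        "mean": np.exp(mean[k]),
                        "sd": np.exp(sd[k]),
                        "q2.5": np.exp(lo[k]),
                        "q97.5": np.exp(hi[k]),
                    }
                )
            else:
                rows.append(
                    {
                        "parameter": lab,
                        "mean": mean[k],
                        "sd": sd[k],
                        "q2.5": lo[k],
                        "q97.5": hi[k],
                    }
                )
    return pd.DataFrame(rows).set_index("parameter")


def correlation_summary(
    chains: ChainSet, convention: str = "cholesky_columns"
) -> dict[str, pd.DataFrame]:
    """Lower-triangular posterior summary of the correlation structure.

    ``full_matrix``: elementwise posterior mean and 95% interval of Omega.
    ``cholesky_columns``: mean/interval of the lower Cholesky factor of
    each Omega draw — the first column equals the correlations with the
    first component, the upper triangle is identically zero, and the
    diagonal degrades below one down the columns (the published layout).
    """
    draws = chains.pooled("omega")  # (s, d, d)
    if convention == "full_matrix":
        mats = draws
    elif convention == "cholesky_columns":
        mats = np.array([np.linalg.cholesky(m) for m in draws])
    else:
        raise ValueError("convention must be 'full_matrix' or 'cholesky_columns'")
    labels = list(chains.labels)
    mean = pd.DataFrame(mats.mean(axis=0), index=labels, columns=labels)
    lo = pd.DataFrame(np.quantile(mats, 0.025, axis=0), index=labels, columns=labels)
    hi = pd.DataFrame(np.quantile(mats, 0.975, axis=0), index=labels, columns=labels)
    return {"mean": mean, "q2.5": lo, "q97.5": hi}
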