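"""Joint probability model for correlated binary defect outcomes.

The latent structure is a multivariate-logit Bernoulli model: for subject
``i`` the vector of log-odds across the d outcome components is

    z_i ~ MVN(mu_i, Sigma),        mu_i = beta^T x_i + b_i * 1,

with ``y_ij ~ Bernoulli(expit(z_ij))`` at observed cells.  The covariance
is separated into scales and a correlation matrix,

    Sigma = diag(tau) * Omega * diag(tau),

with Omega ~ LKJ(eta), tau_j ~ half-Cauchy(0, 2.5), coefficients
beta_pj ~ N(0, sigma2_beta), a shared per-subject random intercept
b_i ~ N(0, sigma2_b), and Gamma(2, rate 0.5) hyperpriors on the variances.

Everything here is an evaluable log-density component; the sampler in
:mod:`dentbayes.mcmc` composes them, and tests check that the composed
joint equals the sum of its parts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .data import AxisKind, DefectPanel

__all__ = [
    "CoefficientMatrix",
    "CovarianceSpec",
    "HyperPriorConfig",
    "ModelConfig",
    "expit",
    "logit",
    "log1pexp",
    "linear_predictor",
    "assemble_covariance",
    "bernoulli_loglik",
    "mvn_logpdf",
    "lkj_logdensity",
    "lkj_log_norm",
    "sample_lkj",
    "cpc_to_cholesky",
    "cholesky_to_cpc",
    "cpc_beta_shapes",
    "halfcauchy_logpdf",
    "gamma_logpdf",
    "log_prior",
    "log_joint",
]

expit = special.expit


def logit(p):
    return special.logit(p)


def log1pexp(z):
    """Overflow-safe log(1 + exp(z))."""
    return np.logaddexp(0.0, z)


@dataclass
class CoefficientMatrix:
    """(p+1) x d fixed effects on the log-odds scale; row 0 is the intercept."""

    beta: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        if not np.isfinite(self.beta).all():
            raise ValueError("coefficient matrix must be finite")

    @property
    def n_components(self) -> int:
        return self.beta.shape[1]


@dataclass
class CovarianceSpec:
    """Scale/correlation separation Sigma = diag(tau) Omega diag(tau)."""

    tau: np.ndarray
    omega: np.ndarray
    eta: float = 1.0

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if np.any(self.tau <= 0):
            raise ValueError("tau must be positive")
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        _check_correlation(self.omega)

    @property
    def sigma(self) -> np.ndarray:
        return assemble_covariance(self.tau, self.omega)


def _check_correlation(omega: np.ndarray) -> None:
    omega = np.asarray(omega, dtype=float)
    if omega.ndim != 2 or omega.shape[0] != omega.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(omega, omega.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(omega), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have unit diagonal")
    eigvals = np.linalg.eigvalsh(omega)
    if eigvals.min() <= 0:
        raise ValueError("correlation matrix must be positive definite")


@dataclass
class HyperPriorConfig:
    """Hyperprior constants.

    Gamma priors are shape-rate and sit on the variances (literal model
    statement; mean = shape/rate = 4).  The Cauchy scale prior is truncated
    to the positive half-line.
    """

    beta_var_shape: float = 2.0
    beta_var_rate: float = 0.5
    b_var_shape: float = 2.0
    b_var_rate: float = 0.5
    zeta_var_shape: float = 2.0
    zeta_var_rate: float = 0.5
    tau_scale: float = 2.5
    eta: float = 1.0
    psi_a: float = 0.5
    psi_b: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "beta_var_shape",
            "beta_var_rate",
            "b_var_shape",
            "b_var_rate",
            "zeta_var_shape",
            "zeta_var_rate",
            "tau_scale",
            "eta",
            "psi_a",
            "psi_b",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ModelConfig:
    """Which model to fit: outcome axis, random effect, GVS, imputation."""

    axis_kind: AxisKind = AxisKind.regions
    include_random_effect: bool = True
    gvs: bool = True
    gvs_threshold: float = 0.6
    imputation: bool = True
    hyper: HyperPriorConfig = field(default_factory=HyperPriorConfig)

    def __post_init__(self) -> None:
        self.axis_kind = AxisKind(self.axis_kind)

    @property
    def n_components(self) -> int:
        return len(self.axis_kind.default_labels)


# ---------------------------------------------------------------------------
# mean structure and covariance


def linear_predictor(
    x_row: np.ndarray, beta: CoefficientMatrix | np.ndarray, b_i: float = 0.0
) -> np.ndarray:
    """Mean vector mu = beta^T x + b_i * 1 for one subject.

    ``x_row`` must carry the leading intercept 1.
    """
    B = beta.beta if isinstance(beta, CoefficientMatrix) else np.asarray(beta)
    x = np.asarray(x_row, dtype=float)
    if x.shape[0] != B.shape[0]:
        raise ValueError(
            f"predictor vector length {x.shape[0]} != coefficient rows {B.shape[0]}"
        )
    return x @ B + b_i


def assemble_covariance(tau: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Sigma = diag(tau) Omega diag(tau); Sigma_jj = tau_j**2."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau must be positive")
    _check_correlation(omega)
    return tau[:, None] * omega * tau[None, :]


def bernoulli_loglik(panel: DefectPanel, z: np.ndarray) -> float:
    """Sum over observed cells of y*z - log(1 + exp(z)); masked cells skip."""
    z = np.asarray(z, dtype=float)
    if z.shape != panel.y.shape:
        raise ValueError("latent logit shape must match panel shape")
    m = panel.observed_mask
    return float(np.sum(panel.y[m] * z[m] - log1pexp(z[m])))


def mvn_logpdf(x: np.ndarray, mean: np.ndarray, sigma: np.ndarray) -> float:
    """Multivariate-normal log-density, summed over rows of ``x``.

    Cholesky-based; near-singular covariances get a 1e-9 diagonal jitter.
    """
    x = np.atleast_2d(x)
    mean = np.broadcast_to(np.atleast_2d(mean), x.shape)
    d = x.shape[1]
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(sigma + 1e-9 * np.eye(d))
    sol = np.linalg.solve(L, (x - mean).T)  # (d, n)
    quad = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return float(np.sum(-0.5 * (quad + logdet + d * np.log(2.0 * np.pi))))


# ---------------------------------------------------------------------------
# LKJ distribution over correlation matrices, via the C-vine construction


def cpc_beta_shapes(d: int, eta: float) -> np.ndarray:
    """Beta shape for each canonical-partial-correlation tree level.

    Level j (1-based column of the Cholesky CPC array) has
    (z+1)/2 ~ Beta(b_j, b_j) with b_j = eta + (d - 1 - j)/2; independent
    levels reproduce LKJ(eta) exactly.
    """
    j = np.arange(1, d)
    return eta + (d - 1 - j) / 2.0


def cpc_to_cholesky(z: np.ndarray) -> np.ndarray:
    """Lower-triangular Cholesky factor of a correlation matrix from CPCs.

    ``z`` is a (d, d) array holding canonical partial correlations strictly
    below the diagonal (entry (i, j), i > j).
    """
    d = z.shape[0]
    L = np.zeros((d, d))
    L[0, 0] = 1.0
    for i in range(1, d):
        rem = 1.0
        for j in range(i):
            L[i, j] = z[i, j] * np.sqrt(rem)
            rem -= L[i, j] ** 2
        if rem <= 0:
            raise ValueError("canonical partial correlations out of range")
        L[i, i] = np.sqrt(rem)
    return L


def cholesky_to_cpc(L: np.ndarray) -> np.ndarray:
    """Invert :func:`cpc_to_cholesky`."""
    d = L.shape[0]
    z = np.zeros((d, d))
    for i in range(1, d):
        rem = 1.0
        for j in range(i):
            z[i, j] = L[i, j] / np.sqrt(rem)
            rem -= L[i, j] ** 2
    return z


def sample_lkj(d: int, eta: float, rng: np.random.Generator) -> np.ndarray:
    """Draw a correlation matrix from LKJ(eta) by the C-vine method."""
    shapes = cpc_beta_shapes(d, eta)
    z = np.zeros((d, d))
    for i in range(1, d):
        for j in range(i):
            b = shapes[j]
            z[i, j] = 2.0 * rng.beta(b, b) - 1.0
    L = cpc_to_cholesky(z)
    omega = L @ L.T
    np.fill_diagonal(omega, 1.0)
    return omega


def lkj_log_norm(d: int, eta: float) -> float:
    """log of the LKJ normalizing constant Z with density det(Omega)^(eta-1)/Z.

    Via the vine factorization: Z = prod_j [2^(2 b_j - 1) B(b_j, b_j)]^(d-j)
    with b_j = eta + (d - 1 - j)/2.
    """
    shapes = cpc_beta_shapes(d, eta)
    j = np.arange(1, d)
    return float(
        np.sum((d - j) * ((2.0 * shapes - 1.0) * np.log(2.0) + special.betaln(shapes, shapes)))
    )


def lkj_logdensity(omega: np.ndarray, eta: float, normalized: bool = False) -> float:
    """LKJ(eta) log-density, proportional to det(Omega)^(eta-1).

    With eta = 1 the density is constant over valid correlation matrices.
    A non-positive-definite matrix is outside the support.
    """
    _check_correlation(omega)
    sign, logdet = np.linalg.slogdet(omega)
    if sign <= 0:
        raise ValueError("correlation matrix must be positive definite")
    out = (eta - 1.0) * logdet
    if normalized:
        out -= lkj_log_norm(omega.shape[0], eta)
    return float(out)


# ---------------------------------------------------------------------------
# scalar prior densities


def halfcauchy_logpdf(x, scale: float = 2.5):
    """log density of the half-Cauchy(0, scale); at x=0 it is log(2/(pi*scale))."""
    x = np.asarray(x, dtype=float)
    out = np.where(
        x < 0,
        -np.inf,
        np.log(2.0) - np.log(np.pi * scale) - np.log1p((x / scale) ** 2),
    )
    return out if out.ndim else float(out)


def gamma_logpdf(x, shape: float, rate: float):
    """Shape-rate Gamma log-density (so Gamma(2, 0.5) has mean 4)."""
    x = np.asarray(x, dtype=float)
    out = np.where(
        x <= 0,
        -np.inf,
        shape * np.log(rate) - special.gammaln(shape) + (shape - 1) * np.log(x) - rate * x,
    )
    return out if out.ndim else float(out)


def log_prior(params: dict, hyper: HyperPriorConfig | None = None) -> float:
    """Sum the log prior over a parameter state dictionary.

    Recognized keys: ``beta`` ((p+1) x d), ``sigma2_beta``, ``b`` (n,),
    ``sigma2_b``, ``tau`` (d,), ``omega`` (d x d), ``indicator`` (p x d) with
    ``psi`` (p x d).  Missing keys contribute nothing; an out-of-support
    value returns -inf; a NaN raises.
    """
    hyper = hyper or HyperPriorConfig()
    total = 0.0
    if "beta" in params:
        beta = np.asarray(params["beta"], dtype=float)
        if np.isnan(beta).any():
            raise ValueError("NaN coefficient")
        s2 = float(params["sigma2_beta"])
        if s2 <= 0:
            return -np.inf
        total += float(np.sum(stats.norm.logpdf(beta, scale=np.sqrt(s2))))
        total += gamma_logpdf(s2, hyper.beta_var_shape, hyper.beta_var_rate)
    if "b" in params and params["b"] is not None:
        b = np.asarray(params["b"], dtype=float)
        s2b = float(params["sigma2_b"])
        if s2b <= 0:
            return -np.inf
        total += float(np.sum(stats.norm.logpdf(b, scale=np.sqrt(s2b))))
        total += gamma_logpdf(s2b, hyper.b_var_shape, hyper.b_var_rate)
    if "tau" in params:
        tau = np.asarray(params["tau"], dtype=float)
        if np.any(tau <= 0):
            return -np.inf
        total += float(np.sum(halfcauchy_logpdf(tau, hyper.tau_scale)))
    if "omega" in params:
        total += lkj_logdensity(np.asarray(params["omega"]), hyper.eta)
    if "indicator" in params and params["indicator"] is not None:
        ind = np.asarray(params["indicator"], dtype=float)
        psi = np.asarray(params["psi"], dtype=float)
        if np.any((psi <= 0) | (psi >= 1)):
            return -np.inf
        total += float(np.sum(ind * np.log(psi) + (1 - ind) * np.log1p(-psi)))
        total += float(
            np.sum(stats.beta.logpdf(psi, hyper.psi_a, hyper.psi_b))
        )
    return total


def log_joint(
    panel: DefectPanel,
    x: np.ndarray,
    params: dict,
    hyper: HyperPriorConfig | None = None,
    imputation_logp: float = 0.0,
) -> float:
    """Full log joint density of data, latents and parameters.

    ``params`` must include ``z`` (n x d latent logits) plus everything
    :func:`log_prior` uses; ``x`` is the complete design matrix (with
    intercept column and any imputed values filled in).  The result equals
    bernoulli_loglik + MVN(z | mu, Sigma) + log_prior + imputation terms —
    an identity the test suite checks against independently computed parts.
    """
    hyper = hyper or HyperPriorConfig()
    z = np.asarray(params["z"], dtype=float)
    beta = np.asarray(params["beta"], dtype=float)
    if "indicator" in params and params["indicator"] is not None:
        ind = np.asarray(params["indicator"], dtype=float)
        full = np.vstack([np.ones((1, beta.shape[1])), ind])
        eff = beta * full
    else:
        eff = beta
    b = params.get("b")
    b_col = np.zeros(panel.n_subjects) if b is None else np.asarray(b, dtype=float)
    mu = x @ eff + b_col[:, None]
    sigma = assemble_covariance(np.asarray(params["tau"]), np.asarray(params["omega"]))
    return (
        bernoulli_loglik(panel, z)
        + mvn_logpdf(z, mu, sigma)
        + log_prior(params, hyper)
        + imputation_logp
    )
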