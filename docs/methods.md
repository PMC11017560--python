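# Methods

## The model

The outcome for subject *i* is a d-vector of binary defect indicators —
one defect scored in the three horizontal regions of the primary maxillary
central incisors (d = 3, order cervical/middle/incisal) or four defect
types scored jointly within one region (d = 4, order EH/OP/PEB/DC). Each
observed cell is Bernoulli with a subject-level latent log-odds vector

    z_i ~ MVN(beta^T x_i + b_i 1, Sigma),   Sigma = diag(tau) Omega diag(tau).

Masked outcome cells simply drop out of the likelihood, so partially
observed subjects are retained (an option to drop fully missing rows
exists, which subsumes both inclusion rules a practitioner might use).

Priors: `beta_pj ~ N(0, sigma2_beta)` with `sigma2_beta ~ Gamma(2, rate
0.5)`; the same Gamma on the random-intercept variance `sigma2_b`;
`tau_j ~ half-Cauchy(0, 2.5)`; `Omega ~ LKJ(eta)` with `eta = 1`
(uniform over valid correlation matrices). The Gamma hyperpriors are taken
literally as shape–rate distributions on the **variances** (mean 4). The
Cauchy scale prior is truncated to the positive half-line, the standard
reading for a scale parameter.

**Random intercept.** `b_i` is one scalar shared across all d components
of a subject's mean vector. A shared intercept is partially confounded
with the compound-symmetric direction of `Sigma`, so the generator default
omits it (`sigma_b = 0`) and the fitter exposes
`include_random_effect` to switch it off; the recovery studies run with it
off so the generating and fitted models coincide exactly.

**Gibbs variable selection.** Every non-intercept coefficient carries an
indicator, `xi_pj = beta_pj I_pj`, `I_pj ~ Bernoulli(psi_pj)`,
`psi_pj ~ Beta(1/2, 1/2)`, with `psi` per predictor-component cell (as
subscripted). When a coefficient is excluded it keeps its full
`N(0, sigma2_beta)` prior — the Kuo–Mallick form, the literal reading of
`xi = beta * I` with the stated priors; no tuned pseudo-prior is needed
because the conjugate coefficient block refreshes excluded coefficients
from their prior every sweep, which serves the same mixing purpose.
Selection uses the strict rule psi-hat > 0.6 in **any** component, and a
selected predictor enters the reduced model in **all** components, which
reproduces the shape of the published reduced-model tables.

**Missing predictors** are parameters updated within the chain (data
assumed missing at random). Continuous columns get a Normal prior centred
at the observed-cell mean (held fixed) with a Gamma(2, 0.5) variance
hyperprior; binary columns a Bernoulli(nu), nu ~ Uniform(0,1); the 3-level
VDBP genotype a multinomial regression on maternal race. The printed
linear-share form of that regression, v = (zeta0 + Race zeta1)/sum(...),
is not a valid simplex map (components can go negative), so the package
implements the standard multinomial-logit (softmax) with the first
category as reference — the conventional meaning of "multinomial
regression". Missing race values are resampled from the empirical level
frequencies tilted by the genotype likelihood. Hyperparameters (nu, the
column variances, zeta) are updated from all cells, observed plus
currently imputed, since the predictors are modelled as realizations of
those priors.

## Sampler

No probabilistic-programming backend is used; the sampler is a blocked
Metropolis-within-Gibbs scheme in numpy/scipy written for this model's
latent-Gaussian structure:

* **z** — column-wise: exact Gaussian conditional draws at masked cells;
  random-walk Metropolis at observed cells with per-column steps adapted
  only during warm-up (target acceptance 0.44).
* **beta** — the regression of z on X is linear with MVN errors, so all
  indicator-active coefficients are drawn jointly from their exact
  multivariate-Gaussian conditional (a ≤ (p+1)d Cholesky solve); inactive
  coefficients are refreshed from the prior.
* **indicators** — exact discrete Gibbs cell by cell in random order with
  rank-one residual bookkeeping; **psi** conjugate Beta.
* **b** — exact Gaussian conditionals.
* **variances, tau, CPCs** — scalar log/atanh random-walk Metropolis.
  `Omega` is parameterized by canonical partial correlations of the
  C-vine; independent scaled-Beta priors on the CPCs (shape
  `eta + (d-1-j)/2` at tree level j) are exactly LKJ(eta), which the test
  suite verifies against the closed-form marginal 2·Beta(1.5,1.5)−1.
* **interweaving** — the latent-logit scale is only weakly identified
  (scaling `beta_.j`, `tau_j` and `z_.j` together changes the likelihood
  only through the saturating Bernoulli term), so centered single-site
  updates random-walk extremely slowly along this ridge. Three
  ancillarity–sufficiency moves fix this: a tau rescale holding
  u = (z − mu)/tau fixed, a CPC move holding the whitened residuals
  L⁻¹D⁻¹(z − mu) fixed, and a per-component group-scale move that
  multiplies (z, beta, tau) by a common factor with the exact Jacobian.
  Without them, fitted correlations on independent-region data sat at
  |r| ≈ 0.3 purely from non-convergence; with them they are ~0.00–0.08
  with split-chain R-hat ≈ 1.05 at the default chain lengths.
* **missing cells** — exact conditionals: Gaussian (continuous),
  two-point (binary), three-point (categorical).

Numerical guards: `log1p(exp(·))` via `logaddexp` for the Bernoulli term;
Cholesky-based MVN densities with a 1e-9 jitter fallback; softmax shifted
by its max; CPC proposals outside the unit ball rejected outright.

Chains are seeded from a single `SeedSequence` spawn, so runs are exactly
reproducible; identical seeds give identical draws. Divergent (non-finite)
states abort with a diagnostic. Convergence is assessed with the
split-chain Gelman–Rubin statistic (flag threshold 1.05, configurable);
non-convergence warns and is recorded in the result, never silent. A
single chain is allowed (split halves) with a warning.

## Identifiability of the latent scale

Because each Bernoulli cell has its own latent logit, the likelihood is
nearly flat along directions that scale a component's coefficients,
latent column and `tau_j` together — the posterior honestly has a long
ridge there, and with the heavy-tailed half-Cauchy prior the scales can
drift well above their generating values at n = 148 (the region whose
prevalence is nearest 1/2 drifts the most). Consequences worth knowing:

* posterior means of coefficients in weakly anchored components inflate in
  magnitude, with correspondingly large posterior SDs — recovery checks
  are therefore made in units of posterior SD (three SDs), not raw
  percentages;
* components anchored by a strong effect or a low prevalence (the
  cervical region in the packaged scenarios) stay well behaved;
* the correlation matrix and the inclusion probabilities are insensitive
  to the ridge once the interweaving moves are in place.

## Synthetic-data generator

`generate_covariates` draws each predictor from a declared distribution;
`generate_outcomes` then follows the model's own data-generating story
(b ~ N(0, sigma_b²), z ~ MVN(beta^T x + b, Sigma), y ~ Bernoulli(expit z)).
The packaged registry (`scenarios.yaml`) carries the enamel-hypoplasia
generating values: 26 coefficient rows (intercept, 23 predictors, two
dummy columns for the 3-level VDBP genotype) by 3 regions, and the 3×3
generating covariances. Scenario 1 uses the full coefficient set with the
application covariance; Scenario 2 the same coefficients with the identity
covariance (independent regions); Scenario 3 a sparse set of seven nonzero
rows of varying strength with the Scenario-1 covariance. Defaults are
n = 148 subjects and 50 iterations.

Covariate distributions are not published, so the defaults are the
field-standard neutral choices: standard normal for continuous columns,
Bernoulli(0.5) for binary, uniform over the three genotype and three race
levels, and Poisson(1) for the salivary strep-mutans count with an
optional upper-truncation cap (off by default, matching the published
generator, whose lack of truncation was flagged there as the cause of
poor recovery for that predictor). All of this is overridable per column
in the scenario config. What the generator does **not** emulate: the real
covariates' scales, skewness and mutual correlations (gestational weeks,
serum concentrations and ages are generated as standardized independent
draws), outcome missingness patterns, and any misclassification of
photographic scoring. Passing recovery tests therefore demonstrate that
the fitter inverts the model's own generating process at the study's
sample size — not that the real-data posteriors are reproduced.

The OP/PEB/DC scenario presets exist in the registry but require
user-supplied coefficient and covariance tables (their generating values
live in supplementary material not redistributed here); PEB Scenario 2 is
deliberately absent because that defect lacked outcomes in two regions.

`run_simulation_study` resamples covariates every iteration (iteration i
uses seed base+i, recorded in the report), runs the full GVS fit, records
inclusion probabilities and posterior means, optionally refits the
reduced model given that iteration's selection, and aggregates MSE/MAE
against the generating truth (NaN-aware: a parameter outside an
iteration's reduced model contributes nothing to that iteration, and a
failed iteration is recorded with its error, never silently dropped).
Reports serialize deterministically (byte-identical JSON for identical
spec, seed and chain config).

## Problem sizes and defaults

Desk-scale defaults are 4 chains × (1,000 warm-up + 1,000 saved) draws —
a Scenario-1 full fit takes ~20 s on one CPU. The published-scale preset
(400,000 burn-in, 2,000 samples) is available as `PAPER_SCALE`. The
bundled recovery tests use one fit each for Scenarios 1 and 2 and ten
replicates at 2 × (600 + 500) for Scenario 3; the acceptance script uses
4 × (3,000 + 2,500) for its single Scenario-1 fit. These sizes were
chosen so the whole suite runs comfortably on a laptop while keeping the
Monte-Carlo error of the checked quantities well inside their tolerances.

## Summary conventions

Coefficient tables can be reported on the odds scale: the exponentiated
posterior mean of the log-odds, the geometric SD `exp(sd(log-odds))`, and
exponentiated equal-tailed 2.5/97.5% quantiles — the convention that
reproduces the published "0.78 (1.11), (0.63, 0.95)" pattern from
log-odds mean −0.248 and SD 0.104. Correlation summaries come in two
conventions: elementwise posterior means/intervals of `Omega`
(`full_matrix`), and means/intervals of the lower-Cholesky factor of each
`Omega` draw (`cholesky_columns`), whose first column equals the
correlations with the first component, whose upper triangle is exactly
zero, and whose diagonal "degrades" below one — the layout of the
published correlation tables.

## Known limitations

* The latent scale ridge above: raw coefficient magnitudes at n = 148 are
  recovered only up to substantial posterior spread.
* One shared `sigma2_beta` across all coefficients and components; with
  predictors on very different scales, standardize before fitting (the
  generator's standard-normal covariates make this moot in simulation).
* The joint region-by-defect (nested) covariance extension and
  DIC/WAIC-based model comparison are out of scope.
* Wishart/inverse-Wishart covariance priors and explicitly spatial
  correlation structures are deliberately not offered; the covariance is
  pairwise between regions or defects.
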