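# dentbayes

Bayesian hierarchical models for **multivariate binary dental-defect
outcomes** — developmental enamel defects (hypoplasia, opacity,
post-eruptive breakdown) and dental caries scored on the primary maxillary
central incisors, either one defect across the three horizontal tooth
regions (cervical, middle, incisal) or several defects jointly within one
region. The package is for biostatisticians and oral-epidemiology
researchers who need correlated-outcome logistic models with built-in
Bayesian variable selection and missing-predictor imputation, and a fully
synthetic simulation path so the method can be exercised without the
(request-only) clinical data.

## Model

For subject *i* with covariate vector *x<sub>i</sub>* (intercept included)
and a d-vector of binary outcomes *y<sub>i</sub>* (d = 3 regions or d = 4
defects):

```
y_ij | z_ij  ~  Bernoulli( expit(z_ij) )            observed cells only
z_i          ~  MVN( mu_i, Sigma )                  latent log-odds
mu_i         =  xi^T x_i + b_i * 1
xi_pj        =  beta_pj * I_pj                      Gibbs variable selection
Sigma        =  diag(tau) * Omega * diag(tau)       scale x correlation
```

with priors `beta_pj ~ N(0, sigma2_beta)`, `sigma2_beta ~ Gamma(2, rate
0.5)` (likewise the random-intercept variance `sigma2_b`), `tau_j ~
half-Cauchy(0, 2.5)`, `Omega ~ LKJ(1)` (uniform over correlation
matrices), `I_pj ~ Bernoulli(psi_pj)`, `psi_pj ~ Beta(1/2, 1/2)`. A
predictor whose posterior inclusion probability exceeds **0.6** in any
outcome component enters the reduced model in all components. Missing
predictor cells are parameters updated inside the MCMC: Normal priors
centred at the observed-cell mean for continuous columns, Bernoulli with a
uniform hyperprior for binary columns, and a multinomial-logit regression
on maternal race for the 3-level VDBP genotype.

Inference is a blocked Metropolis-within-Gibbs sampler written in
numpy/scipy (conjugate Gaussian updates for coefficients and random
effects given the latents, exact discrete Gibbs for indicators and missing
cells, and ancillarity-sufficiency interweaving moves for the weakly
identified latent scales and correlations). See `docs/methods.md`.

## Worked example

`examples/03_simulate_and_fit.py` simulates a cohort of 148 children from
the packaged Scenario-1 generating values (enamel hypoplasia across the
three tooth regions), fits the full model with Gibbs variable selection
(4 chains, 1,500 warm-up + 1,000 saved draws, ~1 minute on one CPU), and
prints, among other things:

```
odds-scale summaries (mean, geometric SD, 95% CI):
                                 mean    sd  q2.5  q97.5
parameter
beta[mother_fvdd_12wk,cervical]  0.19  1.94  0.04   0.48
beta[mother_fvdd_12wk,middle]    1.04  3.70  0.06  15.12
beta[mother_fvdd_12wk,incisal]   0.95  3.77  0.07  15.18
...
posterior mean correlation structure (Cholesky-column convention,
first column reads as plain correlations with the cervical region):
          cervical  middle  incisal
cervical      1.00    0.00     0.00
middle        0.04    0.99     0.00
incisal      -0.16   -0.03     0.96
```

Reading the first row: the mother's functional-vitamin-D-deficiency ratio
at 12 gestational weeks multiplies the odds of a cervical-region defect by
0.19 (95% credible interval 0.04–0.48) per unit increase — the interval
excludes 1, so the fit recovers the strong protective generating effect
(generating log-odds −1.003, i.e. odds 0.37, lie inside the interval),
while the middle/incisal effects are indistinguishable from null, as
generated. The correlation table uses the lower-Cholesky convention in
which the first column is directly interpretable as correlations with the
first component and the diagonal degrades below one down the columns.

The other examples cover data IO and validation (`01`), the log-density
components and the LKJ prior (`02`), missing-predictor imputation (`04`),
and a multi-replicate selection/recovery study (`05`).

A thin CLI wraps the same entry points:

```bash
dentbayes data-validate --panel panel.csv
dentbayes fit --panel panel.csv --predictors x.csv --schema schema.yaml
dentbayes simulate --scenario EH_s3 --iterations 10 --seed 0
```

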