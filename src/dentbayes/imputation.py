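"""Within-MCMC imputation of missing predictor values.

Missing predictors are treated as parameters with their own priors and
iteratively updated inside the sampler (missing-at-random assumption):

* continuous column: Normal(mean of the observed cells, sigma2_col), with
  sigma2_col ~ Gamma(2, rate 0.5);
* binary column: Bernoulli(nu), nu ~ Uniform(0,1) (conjugate Beta update);
* the 3-level VDBP genotype: Multinomial(v1, v2, v3) with category
  probabilities from a multinomial-logit regression on maternal race,
  coefficients zeta ~ N(0, sigma2_zeta), sigma2_zeta ~ Gamma(2, 0.5).

The category-probability map is a softmax with a reference category: the
literal linear-share formula (zeta0 + race*zeta1) / sum(...) is not a valid
simplex map (it can go negative), so the standard multinomial-logit reading
is used — see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ColumnMeta, PredictorTable

__all__ = [
    "ContinuousImputationPrior",
    "BinaryImputationPrior",
    "CategoricalImputationModel",
    "continuous_imputation_prior",
    "binary_imputation_prior",
    "categorical_probabilities",
    "build_imputation_models",
    "imputation_diagnostics",
]


@dataclass
class ContinuousImputationPrior:
    """Normal prior for missing cells of one continuous column."""

    column: str
    mean: float  # arithmetic mean of the observed cells, held fixed
    var_shape: float = 2.0
    var_rate: float = 0.5


@dataclass
class BinaryImputationPrior:
    """Bernoulli(nu) prior with nu ~ Uniform(0,1) for one binary column."""

    column: str
    n_observed_ones: int
    n_observed_zeros: int

    def posterior_mean_nu(self) -> float:
        """Conjugate Beta(1+ones, 1+zeros) mean given the observed cells."""
        a = 1.0 + self.n_observed_ones
        b = 1.0 + self.n_observed_zeros
        return a / (a + b)


@dataclass
class CategoricalImputationModel:
    """Multinomial-logit model for the 3-level VDBP genotype given race."""

    column: str
    levels: tuple[str, ...]
    race_levels: tuple[str, ...]
    # zeta0: (3,) category intercepts; zeta1: (n_race_dummies, 3) race effects.
    # Reference category 0 is pinned at zero for identifiability.
    zeta0: np.ndarray = field(default_factory=lambda: np.zeros(3))
    zeta1: np.ndarray = field(default_factory=lambda: np.zeros((2, 3)))


def continuous_imputation_prior(
    observed_values: np.ndarray, column: str = ""
) -> ContinuousImputationPrior:
    """Prior for a continuous column: Normal centered at the observed mean.

    The variance is a Gamma(2, rate 0.5)-distributed parameter updated in
    the sampler.  An all-missing column has no defensible center; the
    caller must drop it or supply a prior mean explicitly.
    """
    values = np.asarray(observed_values, dtype=float)
    if values.size == 0:
        raise ValueError(
            f"column {column!r} has no observed values; drop the column or "
            "supply a prior mean"
        )
    return ContinuousImputationPrior(column, float(values.mean()))


def binary_imputation_prior(
    observed_values: np.ndarray, column: str = ""
) -> BinaryImputationPrior:
    """Bernoulli(nu) prior with nu ~ Uniform(0,1) for a binary column."""
    values = np.asarray(observed_values, dtype=float)
    ones = int(values.sum())
    return BinaryImputationPrior(column, ones, int(values.size) - ones)


def categorical_probabilities(
    race_dummies: np.ndarray, zeta0: np.ndarray, zeta1: np.ndarray
) -> np.ndarray:
    """Category probabilities v = softmax(zeta0 + race . zeta1).

    ``race_dummies`` may be a scalar, a vector of dummy codes for one
    subject, or an (n, k) matrix; the result is strictly positive and sums
    to one along the category axis.
    """
    zeta0 = np.asarray(zeta0, dtype=float)
    zeta1 = np.atleast_2d(np.asarray(zeta1, dtype=float))
    race = np.asarray(race_dummies, dtype=float)
    if race.ndim == 0:
        race = race.reshape(1, 1)
        if zeta1.shape[0] != 1:
            zeta1 = zeta1.reshape(1, -1)
    elif race.ndim == 1:
        race = race.reshape(1, -1)
    eta = zeta0[None, :] + race @ zeta1
    eta -= eta.max(axis=1, keepdims=True)
    v = np.exp(eta)
    v /= v.sum(axis=1, keepdims=True)
    return v[0] if v.shape[0] == 1 else v


def build_imputation_models(table: PredictorTable) -> dict:
    """Imputation prior for every encoded column that has missing cells.

    Returns a dict with keys ``continuous``, ``binary``, ``categorical``;
    columns with no missing cells create no imputation parameters.
    """
    continuous: list[ContinuousImputationPrior] = []
    binary: list[BinaryImputationPrior] = []
    categorical: list[CategoricalImputationModel] = []
    for meta in table.column_meta:
        idx = table.columns_for(meta.name)
        col_mask = table.observed_mask[:, idx[0]]
        if col_mask.all():
            continue
        if meta.kind == "continuous":
            continuous.append(
                continuous_imputation_prior(table.x[col_mask, idx[0]], meta.name)
            )
        elif meta.kind == "binary":
            binary.append(
                binary_imputation_prior(table.x[col_mask, idx[0]], meta.name)
            )
        else:
            n_race = max(len(table.race_levels) - 1, 1)
            categorical.append(
                CategoricalImputationModel(
                    meta.name,
                    meta.levels,
                    table.race_levels,
                    zeta0=np.zeros(3),
                    zeta1=np.zeros((n_race, 3)),
                )
            )
    return {"continuous": continuous, "binary": binary, "categorical": categorical}


def imputation_diagnostics(table: PredictorTable) -> "pd.DataFrame":
    """Per-encoded-column fraction missing, as a tidy frame."""
    import pandas as pd

    frac = 1.0 - table.observed_mask.mean(axis=0)
    return pd.DataFrame(
        {"column": table.colnames, "fraction_missing": frac}
    ).set_index("column")
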