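"""Synthetic-data generation and the three-scenario recovery study.

The generator draws covariates from per-predictor distributions (standard
normal continuous, Bernoulli binary, uniform categorical genotype, a
truncatable Poisson for the salivary strep-mutans count), then outcomes
from the model's own assumed structure: for each subject

    b ~ N(0, sigma_b^2),  z ~ MVN(beta^T x + b, Sigma),
    y_j ~ Bernoulli(expit(z_j)).

Scenario presets package the published generating values for the
enamel-hypoplasia individual-defect model at n = 148:

* Scenario 1 — full-model posterior-mean coefficients with the
  application's covariance (consistency check);
* Scenario 2 — the same coefficients with independent regions (identity
  covariance; can the fit recover a different correlation structure?);
* Scenario 3 — a sparse coefficient set of varying strength with the
  Scenario-1 covariance (selection behaviour against null predictors).

``run_simulation_study`` repeats generate -> full GVS fit -> threshold
selection -> reduced refit, and aggregates MSE/MAE against the generating
truth plus per-predictor inclusion medians and ranges.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .data import AxisKind, ColumnMeta, DefectPanel, PredictorTable
from .mcmc import ChainSet, McmcConfig, build_design, run_chains
from .model import ModelConfig, expit
from .selection import select_predictors

__all__ = [
    "ScenarioSpec",
    "RecoveryReport",
    "generate_covariates",
    "generate_outcomes",
    "scenario_preset",
    "available_scenarios",
    "run_simulation_study",
    "recovery_error",
    "inclusion_range_summary",
    "mask_missing_at_random",
    "subset_table",
]


def _load_registry() -> dict:
    ref = importlib.resources.files("dentbayes").joinpath("scenarios.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


@dataclass
class ScenarioSpec:
    """Generating truth and study layout for one simulation scenario."""

    name: str
    coefficients: pd.DataFrame  # (p+1) x d, rows = encoded design columns
    covariance: np.ndarray  # d x d generating Sigma
    covariates: list[dict]  # per-predictor distribution configs
    axis_kind: AxisKind = AxisKind.regions
    n: int = 148
    iterations: int = 50
    sigma_b: float = 0.0  # generator default: no subject random effect
    race_spec: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.covariance = np.asarray(self.covariance, dtype=float)
        self.axis_kind = AxisKind(self.axis_kind)
        d = len(self.axis_kind.default_labels)
        if self.covariance.shape != (d, d):
            raise ValueError(f"covariance must be {d}x{d}")
        eig = np.linalg.eigvalsh(self.covariance)
        if eig.min() < -1e-10:
            raise ValueError("covariance must be positive semi-definite")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.coefficients.shape[1] != d:
            raise ValueError("coefficient columns must match the outcome axis")

    @property
    def beta(self) -> np.ndarray:
        return self.coefficients.to_numpy()

    @property
    def labels(self) -> tuple[str, ...]:
        return self.axis_kind.default_labels


def available_scenarios() -> list[str]:
    return sorted(_load_registry()["scenarios"])


def _encoded_names(covariates: list[dict]) -> list[str]:
    names = []
    for cov in covariates:
        if cov["kind"] == "categorical3":
            ref, *others = cov["levels"]
            names += [f"{cov['name']}[{lev}]" for lev in others]
        else:
            names.append(cov["name"])
    return names


def scenario_preset(
    name: str,
    coefficients: dict[str, list[float]] | None = None,
    covariance: np.ndarray | None = None,
    n: int | None = None,
    iterations: int | None = None,
) -> ScenarioSpec:
    """Look up a packaged scenario; rows absent from the coefficient table
    are generated with coefficient zero.

    The OP/PEB/DC presets ship without generating values (their tables are
    supplementary material not redistributed here) and require the
    ``coefficients`` and ``covariance`` arguments.
    """
    registry = _load_registry()
    scenarios = registry["scenarios"]
    if name not in scenarios:
        raise KeyError(
            f"unknown scenario {name!r}; valid presets: {sorted(scenarios)}"
        )
    entry = scenarios[name]
    if entry.get("requires_supplement"):
        if coefficients is None or covariance is None:
            raise ValueError(
                f"scenario {name!r} needs user-supplied coefficients and "
                "covariance (its generating tables are supplementary material)"
            )
        entry = {
            "axis_kind": "regions" if name.startswith(("EH", "OP", "PEB")) else "regions",
            "n": 148,
            "iterations": 50,
            "coefficients": coefficients,
            "covariance": covariance,
            "covariates": registry["covariates"]
            if "covariates" in registry
            else entry.get("covariates"),
        }
    covs = entry["covariates"]
    rownames = ["intercept", *_encoded_names(covs)]
    table = coefficients if coefficients is not None else entry["coefficients"]
    d = len(next(iter(table.values())))
    coef = pd.DataFrame(0.0, index=rownames, columns=list(range(d)))
    for row, values in table.items():
        if row not in coef.index:
            raise KeyError(f"coefficient row {row!r} not a design column")
        coef.loc[row] = values
    spec = ScenarioSpec(
        name=name,
        coefficients=coef,
        covariance=np.asarray(
            covariance if covariance is not None else entry["covariance"], dtype=float
        ),
        covariates=covs,
        axis_kind=entry.get("axis_kind", "regions"),
        n=int(n if n is not None else entry.get("n", 148)),
        iterations=int(
            iterations if iterations is not None else entry.get("iterations", 50)
        ),
        race_spec=registry.get("race", {}),
    )
    spec.coefficients.columns = list(spec.labels)
    return spec


def generate_covariates(
    covariates: list[dict],
    n: int,
    seed: int | np.random.Generator,
    race_spec: dict | None = None,
) -> PredictorTable:
    """Draw a complete covariate table from the declared distributions.

    Supported ``dist`` names: ``normal`` (mean/sd), ``bernoulli`` (p),
    ``categorical`` (levels/probs), ``poisson`` (lam, optional upper
    ``truncate`` cap).  Reproducible given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols, names, metas = [], [], []
    for cov in covariates:
        dist = cov.get("dist", "normal")
        kind = cov["kind"]
        if dist == "normal":
            draw = rng.normal(cov.get("mean", 0.0), cov.get("sd", 1.0), size=n)
        elif dist == "bernoulli":
            draw = (rng.random(n) < cov.get("p", 0.5)).astype(float)
        elif dist == "poisson":
            draw = rng.poisson(cov.get("lam", 1.0), size=n).astype(float)
            cap = cov.get("truncate")
            if cap is not None:
                draw = np.minimum(draw, float(cap))
        elif dist == "categorical":
            levels = [str(v) for v in cov["levels"]]
            probs = cov.get("probs") or [1.0 / len(levels)] * len(levels)
            idx = rng.choice(len(levels), size=n, p=probs)
            metas.append(ColumnMeta(cov["name"], "categorical3", tuple(levels)))
            for k, lev in enumerate(levels[1:], start=1):
                cols.append((idx == k).astype(float))
                names.append(f"{cov['name']}[{lev}]")
            continue
        else:
            raise ValueError(f"unknown distribution {dist!r} for {cov['name']!r}")
        metas.append(ColumnMeta(cov["name"], kind if kind != "categorical3" else kind))
        cols.append(draw)
        names.append(cov["name"])
    race = None
    race_levels: tuple[str, ...] = ()
    if race_spec and race_spec.get("levels"):
        race_levels = tuple(str(v) for v in race_spec["levels"])
        race = np.array(
            [race_levels[i] for i in rng.choice(len(race_levels), size=n)],
            dtype=object,
        )
    x = np.column_stack(cols) if cols else np.zeros((n, 0))
    return PredictorTable(
        x, names, metas, np.ones_like(x, dtype=bool), race, race_levels
    )


def _psd_factor(sigma: np.ndarray) -> np.ndarray:
    """Matrix square root tolerant of semi-definite (even zero) covariance."""
    vals, vecs = np.linalg.eigh(sigma)
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def generate_outcomes(
    beta: np.ndarray,
    sigma: np.ndarray,
    sigma_b: float,
    x_design: np.ndarray,
    seed: int | np.random.Generator,
    axis_kind: AxisKind | str = AxisKind.regions,
) -> DefectPanel:
    """Draw an outcome panel from the latent multivariate-logit model.

    ``x_design`` must carry the leading intercept column; ``sigma`` may be
    positive semi-definite (a zero matrix gives deterministic logits).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    axis_kind = AxisKind(axis_kind)
    beta = np.asarray(beta, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    n = x_design.shape[0]
    d = beta.shape[1]
    eig = np.linalg.eigvalsh(sigma)
    if eig.min() < -1e-10:
        raise ValueError("generating covariance must be positive semi-definite")
    mu = x_design @ beta
    if sigma_b > 0:
        mu += rng.normal(0.0, sigma_b, size=n)[:, None]
    z = mu + rng.standard_normal((n, d)) @ _psd_factor(sigma).T
    y = (rng.random((n, d)) < expit(z)).astype(float)
    return DefectPanel(
        list(range(n)),
        y,
        np.ones((n, d), dtype=bool),
        axis_kind,
        axis_kind.default_labels,
    )


def subset_table(table: PredictorTable, encoded_columns: list[str]) -> PredictorTable:
    """Restrict a predictor table to a subset of encoded columns (for
    reduced-model refits)."""
    idx = [table.colnames.index(c) for c in encoded_columns]
    kept_meta = []
    for meta in table.column_meta:
        if meta.kind == "categorical3":
            if any(c.startswith(meta.name + "[") for c in encoded_columns):
                kept_meta.append(meta)
        elif meta.name in encoded_columns:
            kept_meta.append(meta)
    return PredictorTable(
        table.x[:, idx],
        [table.colnames[i] for i in idx],
        kept_meta,
        table.observed_mask[:, idx],
        table.race,
        table.race_levels,
    )


def mask_missing_at_random(
    table: PredictorTable,
    columns: list[str],
    rate: float,
    seed: int | np.random.Generator,
) -> PredictorTable:
    """Delete cells completely at random in the named encoded columns."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = table.observed_mask.copy()
    for col in columns:
        j = table.colnames.index(col)
        drop = rng.random(table.n_subjects) < rate
        mask[drop, j] = False
    return PredictorTable(
        table.x.copy(), list(table.colnames), list(table.column_meta), mask,
        table.race, table.race_levels,
    )


# ---------------------------------------------------------------------------
# recovery metrics


def recovery_error(
    estimates: np.ndarray, truth: np.ndarray, metric: str = "MSE"
) -> np.ndarray:
    """Per-parameter error of per-iteration estimates against the truth.

    ``estimates`` stacks iterations on axis 0; NaN cells (a parameter not
    estimated in that iteration, e.g. not selected) are skipped so every
    cell's denominator is its own number of contributing iterations.
    """
    estimates = np.asarray(estimates, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimates.shape[1:] != truth.shape:
        raise ValueError("estimate stack and truth shapes disagree")
    dev = estimates - truth
    with np.errstate(invalid="ignore"):
        if metric.upper() == "MSE":
            return np.nanmean(dev**2, axis=0)
        if metric.upper() == "MAE":
            return np.nanmean(np.abs(dev), axis=0)
    raise ValueError("metric must be 'MSE' or 'MAE'")


def inclusion_range_summary(
    psi_stack: np.ndarray,
    predictor_names: list[str],
    component_labels: tuple[str, ...],
    threshold: float = 0.6,
) -> pd.DataFrame:
    """Median / min / max inclusion probability per predictor-component.

    A cell whose whole range exceeds the threshold is flagged
    ``consistently_inclusive`` (box-plot-ready long format).
    """
    stack = np.asarray(psi_stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("psi stack must be (iterations, predictors, components)")
    rows = []
    for p, name in enumerate(predictor_names):
        for j, lab in enumerate(component_labels):
            vals = stack[:, p, j]
            rows.append(
                {
                    "predictor": name,
                    "component": lab,
                    "median": float(np.median(vals)),
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                    "consistently_inclusive": bool(vals.min() > threshold),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class RecoveryReport:
    """Per-iteration records and aggregate recovery metrics."""

    scenario: str
    truth: pd.DataFrame
    sigma_truth: np.ndarray
    iterations: list[dict]
    psi_stack: np.ndarray  # (iters, p, d), NaN rows for failed iterations
    beta_full_stack: np.ndarray  # full-model posterior means
    beta_reduced_stack: np.ndarray  # reduced-model means, NaN where excluded
    sigma_stack: np.ndarray  # posterior-mean Sigma per iteration
    base_seed: int

    @property
    def n_failed(self) -> int:
        return sum(1 for it in self.iterations if it.get("failed"))

    def mse(self, which: str = "reduced") -> pd.DataFrame:
        stack = self.beta_reduced_stack if which == "reduced" else self.beta_full_stack
        return pd.DataFrame(
            recovery_error(stack, self.truth.to_numpy(), "MSE"),
            index=self.truth.index,
            columns=self.truth.columns,
        )

    def mae(self, which: str = "reduced") -> pd.DataFrame:
        stack = self.beta_reduced_stack if which == "reduced" else self.beta_full_stack
        return pd.DataFrame(
            recovery_error(stack, self.truth.to_numpy(), "MAE"),
            index=self.truth.index,
            columns=self.truth.columns,
        )

    def sigma_error(self, metric: str = "MSE") -> np.ndarray:
        return recovery_error(self.sigma_stack, self.sigma_truth, metric)

    def inclusion_summary(self, threshold: float = 0.6) -> pd.DataFrame:
        ok = ~np.isnan(self.psi_stack).all(axis=(1, 2))
        return inclusion_range_summary(
            self.psi_stack[ok],
            list(self.truth.index[1:]),
            tuple(self.truth.columns),
            threshold,
        )

    def to_json(self, path=None) -> str:
        """Deterministic serialization of the whole report."""
        payload = {
            "scenario": self.scenario,
            "base_seed": self.base_seed,
            "truth": self.truth.round(10).to_dict(orient="split"),
            "sigma_truth": np.round(self.sigma_truth, 10).tolist(),
            "n_failed": self.n_failed,
            "iteration_seeds": [it.get("seed") for it in self.iterations],
            "psi_stack": np.round(self.psi_stack, 10).tolist(),
            "beta_full_stack": np.round(self.beta_full_stack, 10).tolist(),
            "beta_reduced_stack": np.round(self.beta_reduced_stack, 10).tolist(),
            "sigma_stack": np.round(self.sigma_stack, 10).tolist(),
        }
        text = json.dumps(payload, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def run_simulation_study(
    spec: ScenarioSpec,
    mcmc: McmcConfig | None = None,
    seed: int | None = None,
    iterations: int | None = None,
    threshold: float = 0.6,
    refit_reduced: bool = True,
    include_random_effect: bool = False,
) -> RecoveryReport:
    """Run the generate / GVS-fit / reduce / refit loop for one scenario.

    Covariates are resampled each iteration; iteration i uses seed
    ``base_seed + i`` (recorded in the report).  A failed iteration is
    recorded with its error and its metric rows are NaN — never silently
    dropped from denominators.
    """
    mcmc = mcmc or McmcConfig()
    base_seed = int(seed if seed is not None else mcmc.seed)
    iters = int(iterations if iterations is not None else spec.iterations)
    p1, d = spec.beta.shape
    psi_stack = np.full((iters, p1 - 1, d), np.nan)
    beta_full = np.full((iters, p1, d), np.nan)
    beta_reduced = np.full((iters, p1, d), np.nan)
    sigma_stack = np.full((iters, d, d), np.nan)
    records: list[dict] = []
    cfg_full = ModelConfig(
        axis_kind=spec.axis_kind,
        include_random_effect=include_random_effect,
        gvs=True,
        gvs_threshold=threshold,
        imputation=False,
    )
    for it in range(iters):
        it_seed = base_seed + it
        record: dict = {"seed": it_seed}
        try:
            ss = np.random.SeedSequence(it_seed).spawn(3)
            sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
            table = generate_covariates(
                spec.covariates, spec.n, sub[0], spec.race_spec
            )
            X, design_cols, _ = build_design(table)
            panel = generate_outcomes(
                spec.beta, spec.covariance, spec.sigma_b, X, sub[1], spec.axis_kind
            )
            chains = run_chains(
                panel,
                table,
                cfg_full,
                McmcConfig(
                    n_chains=mcmc.n_chains,
                    warmup=mcmc.warmup,
                    samples=mcmc.samples,
                    thin=mcmc.thin,
                    seed=sub[2],
                    check_convergence=False,
                ),
            )
            psi_hat = chains.pooled("indicator").mean(axis=0)
            psi_stack[it] = psi_hat
            beta_full[it] = chains.pooled("beta").mean(axis=0)
            sigma_stack[it] = _posterior_mean_sigma(chains)
            report = select_predictors(
                psi_hat, table.colnames, spec.labels, threshold
            )
            record["selected"] = report.selected
            record["psi_hat"] = psi_hat
            if refit_reduced:
                beta_reduced[it] = _reduced_refit(
                    panel, table, report.selected, spec, cfg_full, mcmc, sub[2]
                )
        except Exception as err:  # noqa: BLE001 — recorded, never dropped
            record["failed"] = True
            record["error"] = f"{type(err).__name__}: {err}"
        records.append(record)
    return RecoveryReport(
        scenario=spec.name,
        truth=spec.coefficients,
        sigma_truth=spec.covariance,
        iterations=records,
        psi_stack=psi_stack,
        beta_full_stack=beta_full,
        beta_reduced_stack=beta_reduced,
        sigma_stack=sigma_stack,
        base_seed=base_seed,
    )


def _posterior_mean_sigma(chains: ChainSet) -> np.ndarray:
    tau = chains.pooled("tau")  # (s, d)
    omega = chains.pooled("omega")  # (s, d, d)
    sig = tau[:, :, None] * omega * tau[:, None, :]
    return sig.mean(axis=0)


def _reduced_refit(panel, table, selected, spec, cfg_full, mcmc, seed):
    """Fit the reduced model (selected predictors in all components) and
    map its posterior means back onto the full coefficient grid."""
    p1, d = spec.beta.shape
    out = np.full((p1, d), np.nan)
    rownames = list(spec.coefficients.index)
    cfg = ModelConfig(
        axis_kind=cfg_full.axis_kind,
        include_random_effect=cfg_full.include_random_effect,
        gvs=False,
        imputation=False,
    )
    red_table = subset_table(table, selected) if selected else subset_table(table, [])
    chains = run_chains(
        panel,
        red_table,
        cfg,
        McmcConfig(
            n_chains=mcmc.n_chains,
            warmup=mcmc.warmup,
            samples=mcmc.samples,
            thin=mcmc.thin,
            seed=seed + 1,
            check_convergence=False,
        ),
    )
    means = chains.pooled("beta").mean(axis=0)  # (1+len(selected), d)
    out[0] = means[0]
    for k, name in enumerate(selected):
        out[rownames.index(name)] = means[k + 1]
    return out
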