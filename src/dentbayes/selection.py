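"""Gibbs variable selection: indicator-masked coefficients and thresholding.

Each non-intercept coefficient beta_pj is paired with a binary indicator
I_pj ~ Bernoulli(psi_pj), psi_pj ~ Beta(1/2, 1/2); the effective
coefficient entering the mean structure is xi_pj = beta_pj * I_pj
(Kuo-Mallick form: an excluded coefficient keeps its full prior).  The
posterior mean of I_pj is the inclusion probability; a predictor whose
inclusion probability strictly exceeds the threshold (default 0.6) in at
least one outcome component enters the reduced model in ALL components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "InclusionState",
    "effective_coefficients",
    "inclusion_probability",
    "select_predictors",
    "build_reduced_spec",
    "SelectionReport",
]


@dataclass
class InclusionState:
    """Current GVS state: indicators, inclusion probabilities, effective xi."""

    indicators: np.ndarray  # (p, d) in {0,1}, intercept excluded
    psi: np.ndarray  # (p, d) in (0,1)

    def __post_init__(self) -> None:
        self.indicators = np.asarray(self.indicators, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.indicators.shape != self.psi.shape:
            raise ValueError("indicator and psi shapes must agree")
        if not np.isin(self.indicators, (0.0, 1.0)).all():
            raise ValueError("indicators must be 0/1")
        if np.any((self.psi <= 0) | (self.psi >= 1)):
            raise ValueError("psi must lie strictly in (0,1)")


def effective_coefficients(beta: np.ndarray, indicators: np.ndarray) -> np.ndarray:
    """xi = beta * I elementwise; the intercept row passes through unchanged.

    ``beta`` is (p+1) x d including the intercept row; ``indicators`` is
    p x d for the non-intercept rows.
    """
    beta = np.asarray(beta, dtype=float)
    indicators = np.asarray(indicators, dtype=float)
    if beta.shape[0] != indicators.shape[0] + 1 or beta.shape[1] != indicators.shape[1]:
        raise ValueError(
            f"beta {beta.shape} incompatible with indicators {indicators.shape}"
        )
    xi = beta.copy()
    xi[1:] *= indicators
    return xi


def inclusion_probability(indicator_draws: np.ndarray) -> np.ndarray:
    """Elementwise mean of indicator draws (draws stacked on axis 0)."""
    draws = np.asarray(indicator_draws, dtype=float)
    if draws.size == 0 or draws.shape[0] == 0:
        raise ValueError("need at least one indicator draw")
    return draws.mean(axis=0)


@dataclass
class SelectionReport:
    """Selected predictors with the components where each passed threshold."""

    selected: list[str]
    components_by_predictor: dict[str, list[str]]
    psi_hat: pd.DataFrame
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        frame = self.psi_hat.copy()
        frame["selected"] = [p in self.selected for p in frame.index]
        return frame


def select_predictors(
    psi_hat: np.ndarray,
    predictor_names: list[str],
    component_labels: list[str] | tuple[str, ...],
    threshold: float = 0.6,
) -> SelectionReport:
    """Predictors whose inclusion probability strictly exceeds the threshold.

    The rule is any-component: one qualifying component selects the
    predictor; a value exactly at the threshold does not qualify.
    """
    psi_hat = np.asarray(psi_hat, dtype=float)
    if psi_hat.shape != (len(predictor_names), len(component_labels)):
        raise ValueError("psi_hat shape must be (n_predictors, n_components)")
    selected: list[str] = []
    comp_map: dict[str, list[str]] = {}
    for p, name in enumerate(predictor_names):
        hits = [
            lab for j, lab in enumerate(component_labels) if psi_hat[p, j] > threshold
        ]
        if hits:
            selected.append(name)
            comp_map[name] = hits
    frame = pd.DataFrame(
        psi_hat, index=list(predictor_names), columns=list(component_labels)
    )
    return SelectionReport(selected, comp_map, frame, threshold)


def build_reduced_spec(
    selected: list[str],
    all_predictors: list[str],
) -> dict:
    """Reduced-model configuration: selected predictors in all components.

    Returns the encoded-column subset (intercept implicit) and flags GVS
    off for the reduced fit; an empty selection yields an intercept-only
    model with a warning flag.
    """
    unknown = [s for s in selected if s not in all_predictors]
    if unknown:
        raise ValueError(f"selected predictors not in design: {unknown}")
    keep = [p for p in all_predictors if p in selected]
    return {
        "predictors": keep,
        "gvs": False,
        "intercept_only": not keep,
    }
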