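"""Outcome panels and predictor tables for tooth-region defect models.

The observational unit is a child; the outcome is a panel of binary defect
indicators with one of two component axes:

* ``regions`` — one defect scored in the three horizontal regions of the
  primary maxillary central incisors, ordered (cervical, middle, incisal);
* ``defects`` — four defect types scored jointly within a single region,
  ordered (EH, OP, PEB, DC): enamel hypoplasia, opacity, post-eruptive
  breakdown, dental caries.

Missing cells are first-class: a boolean mask accompanies every panel and
predictor matrix, and downstream likelihoods simply skip masked outcome
cells while masked predictor cells are imputed within the MCMC.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

REGION_LABELS = ("cervical", "middle", "incisal")
DEFECT_LABELS = ("EH", "OP", "PEB", "DC")

NA_TOKENS = ("", "NA")


class AxisKind(str, enum.Enum):
    """Which component axis the outcome panel carries."""

    regions = "regions"
    defects = "defects"

    @property
    def default_labels(self) -> tuple[str, ...]:
        return REGION_LABELS if self is AxisKind.regions else DEFECT_LABELS


class ValidationError(ValueError):
    """A cell or column violates the declared domain."""


class ConfigurationError(ValueError):
    """The file or schema does not match what was declared."""


@dataclass
class DefectPanel:
    """Binary outcome array (subject x component) with a missingness mask."""

    subject_ids: list
    y: np.ndarray  # (n, d) float/int; only observed cells are meaningful
    observed_mask: np.ndarray  # (n, d) bool
    axis_kind: AxisKind
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        self.axis_kind = AxisKind(self.axis_kind)
        self.labels = tuple(self.labels)
        if self.y.shape != self.observed_mask.shape:
            raise ValidationError("mask shape must equal outcome shape")
        if self.y.ndim != 2:
            raise ValidationError("outcome array must be 2-D (subject x component)")
        expected = len(self.axis_kind.default_labels)
        if self.y.shape[1] != expected:
            raise ValidationError(
                f"axis_kind={self.axis_kind.value} requires {expected} components, "
                f"got {self.y.shape[1]}"
            )
        if len(self.labels) != self.y.shape[1]:
            raise ValidationError("label count must match component count")
        if self.n_subjects < 1:
            raise ValidationError("panel needs at least one subject")
        observed = self.y[self.observed_mask]
        if observed.size and not np.isin(observed, (0.0, 1.0)).all():
            raise ValidationError("observed outcome cells must be 0 or 1")

    @property
    def n_subjects(self) -> int:
        return self.y.shape[0]

    @property
    def n_components(self) -> int:
        return self.y.shape[1]

    def drop_fully_missing(self) -> "DefectPanel":
        """Return a panel without subjects whose every component is missing."""
        keep = self.observed_mask.any(axis=1)
        return DefectPanel(
            [s for s, k in zip(self.subject_ids, keep) if k],
            self.y[keep],
            self.observed_mask[keep],
            self.axis_kind,
            self.labels,
        )


@dataclass
class ColumnMeta:
    """Declared kind of one original (pre-encoding) predictor."""

    name: str
    kind: str  # continuous | binary | categorical3
    levels: tuple[str, ...] | None = None  # categorical3 only; first = reference

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "categorical3"):
            raise ConfigurationError(f"unknown predictor kind {self.kind!r}")
        if self.kind == "categorical3":
            if not self.levels or len(self.levels) != 3:
                raise ConfigurationError(
                    f"categorical3 predictor {self.name!r} needs exactly 3 levels"
                )
            self.levels = tuple(str(v) for v in self.levels)


@dataclass
class PredictorTable:
    """Dummy-encoded n x p predictor matrix with missingness mask.

    ``race`` is the auxiliary 3-level maternal-race column used only by the
    VDBP imputation model; it is never part of the design matrix.
    """

    x: np.ndarray  # (n, p) after dummy-encoding
    colnames: list[str]
    column_meta: list[ColumnMeta]
    observed_mask: np.ndarray  # (n, p) bool
    race: np.ndarray | None = None  # (n,) object array of level names or None
    race_levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if self.x.shape != self.observed_mask.shape:
            raise ValidationError("predictor mask shape must equal matrix shape")
        if len(self.colnames) != self.x.shape[1]:
            raise ValidationError("column name count must match matrix width")
        if self.race is not None and len(self.race_levels) > 3:
            raise ValidationError("race has at most 3 levels")

    @property
    def n_subjects(self) -> int:
        return self.x.shape[0]

    @property
    def n_columns(self) -> int:
        return self.x.shape[1]

    def columns_for(self, predictor: str) -> list[int]:
        """Indices of the encoded column(s) belonging to one predictor."""
        meta = next((m for m in self.column_meta if m.name == predictor), None)
        if meta is None:
            raise KeyError(predictor)
        if meta.kind == "categorical3":
            return [
                j
                for j, c in enumerate(self.colnames)
                if c.startswith(meta.name + "[")
            ]
        return [self.colnames.index(meta.name)]

    @property
    def predictor_names(self) -> list[str]:
        return [m.name for m in self.column_meta]


def _parse_cell(raw, row: int, col: str) -> tuple[float, bool]:
    """Return (value, observed) for one outcome cell."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return 0.0, False
    text = str(raw).strip()
    if text in NA_TOKENS:
        return 0.0, False
    try:
        value = float(text)
    except ValueError:
        raise ValidationError(
            f"row {row}, column {col!r}: cell {raw!r} is not 0/1/NA"
        ) from None
    if value not in (0.0, 1.0):
        raise ValidationError(
            f"row {row}, column {col!r}: cell {raw!r} outside {{0, 1, NA}}"
        )
    return value, True


def read_panel(
    path: str | Path,
    axis_kind: AxisKind | str,
    labels: Sequence[str] | None = None,
    subject_column: str = "subject_id",
) -> DefectPanel:
    """Read a defect panel from a UTF-8 CSV with a header row.

    Cells parseable as 0/1 become observed; empty or ``NA`` cells are masked
    missing; any other value is a validation error naming the row and column.
    Row order is preserved.
    """
    axis_kind = AxisKind(axis_kind)
    labels = tuple(labels) if labels is not None else axis_kind.default_labels
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in labels if c not in frame.columns]
    if missing_cols:
        raise ConfigurationError(f"panel file lacks columns {missing_cols}")
    if subject_column in frame.columns:
        subject_ids = frame[subject_column].tolist()
    else:
        subject_ids = list(range(len(frame)))
    n, d = len(frame), len(labels)
    y = np.zeros((n, d))
    mask = np.zeros((n, d), dtype=bool)
    for j, lab in enumerate(labels):
        for i, raw in enumerate(frame[lab]):
            y[i, j], mask[i, j] = _parse_cell(raw, i, lab)
    return DefectPanel(subject_ids, y, mask, axis_kind, labels)


def write_panel(panel: DefectPanel, path: str | Path) -> None:
    """Write a panel back to CSV; masked cells become ``NA``."""
    data = {"subject_id": panel.subject_ids}
    for j, lab in enumerate(panel.labels):
        col = []
        for i in range(panel.n_subjects):
            col.append(str(int(panel.y[i, j])) if panel.observed_mask[i, j] else "NA")
        data[lab] = col
    pd.DataFrame(data).to_csv(path, index=False)


def load_schema(path: str | Path) -> tuple[list[ColumnMeta], dict]:
    """Load a YAML/JSON predictor schema.

    Expected layout::

        predictors:
          - {name: gestational_age, kind: continuous}
          - {name: vdbp, kind: categorical3, levels: ["1s", "1f", "2"]}
        race: {name: maternal_race, levels: [African American, Caucasian, Hispanic]}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    metas = [
        ColumnMeta(p["name"], p["kind"], tuple(p.get("levels", ()) or ()) or None)
        for p in raw["predictors"]
    ]
    return metas, raw.get("race") or {}


def read_predictors(
    path: str | Path,
    schema: Sequence[ColumnMeta],
    race_spec: dict | None = None,
) -> PredictorTable:
    """Read and dummy-encode a predictor table from CSV.

    categorical3 predictors expand to exactly two dummy columns with the
    first declared level as the reference; a missing categorical cell masks
    both dummies. Continuous columns stay on their native scale.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    n = len(frame)
    cols: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    names: list[str] = []
    for meta in schema:
        if meta.name not in frame.columns:
            raise ConfigurationError(f"predictor file lacks column {meta.name!r}")
        raw = frame[meta.name].tolist()
        observed = np.array([str(v).strip() not in NA_TOKENS for v in raw])
        if meta.kind == "categorical3":
            ref, *others = meta.levels
            dummies = np.zeros((n, 2))
            for i, v in enumerate(raw):
                if not observed[i]:
                    continue
                text = str(v).strip()
                if text not in meta.levels:
                    raise ValidationError(
                        f"row {i}, column {meta.name!r}: level {v!r} not in "
                        f"{list(meta.levels)}"
                    )
                for k, lev in enumerate(others):
                    dummies[i, k] = float(text == lev)
            for k, lev in enumerate(others):
                cols.append(dummies[:, k])
                masks.append(observed.copy())
                names.append(f"{meta.name}[{lev}]")
        else:
            values = np.zeros(n)
            for i, v in enumerate(raw):
                if not observed[i]:
                    continue
                try:
                    values[i] = float(str(v).strip())
                except ValueError:
                    raise ValidationError(
                        f"row {i}, column {meta.name!r}: {v!r} is not numeric"
                    ) from None
                if meta.kind == "binary" and values[i] not in (0.0, 1.0):
                    raise ValidationError(
                        f"row {i}, column {meta.name!r}: binary value {v!r} "
                        "outside {0, 1}"
                    )
            if not observed.any():
                warnings.warn(
                    f"predictor column {meta.name!r} is entirely missing",
                    stacklevel=2,
                )
            cols.append(values)
            masks.append(observed)
            names.append(meta.name)
    race = None
    race_levels: tuple[str, ...] = ()
    if race_spec and race_spec.get("name") in frame.columns:
        race_levels = tuple(str(v) for v in race_spec.get("levels", ()))
        raw = frame[race_spec["name"]].tolist()
        race = np.array(
            [str(v).strip() if str(v).strip() not in NA_TOKENS else None for v in raw],
            dtype=object,
        )
        bad = {
            str(v).strip()
            for v in race[race != None]  # noqa: E711 — object-array comparison
            if race_levels and str(v).strip() not in race_levels
        }
        if bad:
            raise ValidationError(f"race levels {sorted(bad)} not in {list(race_levels)}")
    return PredictorTable(
        np.column_stack(cols) if cols else np.zeros((n, 0)),
        names,
        list(schema),
        np.column_stack(masks) if masks else np.zeros((n, 0), dtype=bool),
        race,
        race_levels,
    )


def summarize_prevalence(panel: DefectPanel) -> pd.DataFrame:
    """Per-component defect prevalence over observed cells only.

    Denominators differ across components when missingness differs; a
    component with zero observed cells gets an undefined (NaN) percent.
    """
    rows = []
    for j, lab in enumerate(panel.labels):
        obs = panel.observed_mask[:, j]
        count_observed = int(obs.sum())
        count_present = int(panel.y[obs, j].sum())
        percent = (
            100.0 * count_present / count_observed if count_observed else np.nan
        )
        rows.append(
            {
                "component": lab,
                "count_present": count_present,
                "count_observed": count_observed,
                "percent": percent,
            }
        )
    return pd.DataFrame(rows).set_index("component")
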