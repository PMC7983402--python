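"""Patient-level data model and run configuration.

A development dataset is a binary outcome vector plus a predictor matrix with
per-column metadata (type, forced-in-model flag, spline-eligibility flag).
Categorical predictors are stored as integer level codes with the label list
kept in the metadata; missing cells are tracked by an explicit boolean mask,
never by sentinel values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PredictorMeta",
    "PatientTable",
    "StoppingRule",
    "AccrualConfig",
    "SchemaError",
    "ValidationError",
    "read_patient_table",
    "write_patient_table",
    "event_fraction",
]

VTYPES = ("continuous", "binary", "categorical")


class SchemaError(ValueError):
    """A column or type in the input does not match the declared schema."""


class ValidationError(ValueError):
    """Input values violate a data-model invariant."""


@dataclass(frozen=True)
class PredictorMeta:
    """Metadata for one predictor column.

    Parameters
    ----------
    name : str
        Column name as it appears in the CSV header.
    vtype : {"continuous", "binary", "categorical"}
        Variable type. Two-level variables are ``binary``; ``categorical``
        requires at least three levels and is reference-coded at
        design-matrix time (first listed level is the reference).
    levels : tuple of str, optional
        Ordered level labels, categorical only.
    forced : bool
        Never eliminated by backward selection.
    spline : bool
        Eligible for restricted-cubic-spline expansion (continuous only).
    """

    name: str
    vtype: str
    levels: tuple[str, ...] | None = None
    forced: bool = False
    spline: bool = False

    def __post_init__(self) -> None:
        if self.vtype not in VTYPES:
            raise SchemaError(f"unknown vtype {self.vtype!r} for {self.name!r}")
        if self.spline and self.vtype != "continuous":
            raise SchemaError(
                f"{self.name!r}: spline expansion requires a continuous predictor"
            )
        if self.vtype == "categorical":
            if self.levels is None or len(self.levels) < 3:
                raise SchemaError(
                    f"{self.name!r}: categorical predictors need >= 3 levels "
                    "(use vtype='binary' for two-level variables)"
                )
            object.__setattr__(self, "levels", tuple(str(v) for v in self.levels))
        elif self.levels is not None:
            raise SchemaError(f"{self.name!r}: levels only apply to categoricals")


class PatientTable:
    """Outcome vector plus predictor columns with an explicit missingness mask.

    Columns are stored as float arrays (categorical columns as level codes
    ``0..L-1``); missing cells hold NaN *and* are flagged in ``missing``.
    """

    def __init__(
        self,
        y: Sequence[int] | np.ndarray,
        columns: Mapping[str, np.ndarray],
        meta: Sequence[PredictorMeta],
        missing: Mapping[str, np.ndarray] | None = None,
    ) -> None:
        y = np.asarray(y)
        if y.ndim != 1:
            raise ValidationError("outcome must be a 1-d vector")
        yv = np.unique(y[~pd.isna(y)])
        if not np.all(np.isin(yv, [0, 1])):
            raise ValidationError(f"outcome must be coded 0/1, found {yv.tolist()}")
        if np.any(pd.isna(np.asarray(y, dtype=float))):
            raise ValidationError("outcome contains missing values")
        self.y = y.astype(np.int8)
        self.meta = tuple(meta)
        names = [m.name for m in self.meta]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate predictor names in schema")
        if set(columns) != set(names):
            raise SchemaError(
                f"columns {sorted(columns)} do not match schema {sorted(names)}"
            )
        n = len(self.y)
        self.columns: dict[str, np.ndarray] = {}
        self.missing: dict[str, np.ndarray] = {}
        for m in self.meta:
            col = np.asarray(columns[m.name], dtype=float)
            if col.shape != (n,):
                raise ValidationError(f"column {m.name!r} length != outcome length")
            mask = (
                np.asarray(missing[m.name], dtype=bool)
                if missing is not None and m.name in missing
                else np.isnan(col)
            )
            col = col.copy()
            col[mask] = np.nan
            self.columns[m.name] = col
            self.missing[m.name] = mask.copy()
            obs = col[~mask]
            if m.vtype == "binary":
                bad = obs[~np.isin(obs, [0.0, 1.0])]
                if bad.size:
                    raise ValidationError(f"binary column {m.name!r} has values {bad[:3]}")
            elif m.vtype == "categorical":
                codes = obs[~np.isin(obs, np.arange(len(m.levels)))]
                if codes.size:
                    raise ValidationError(
                        f"categorical column {m.name!r} has codes outside 0..{len(m.levels) - 1}"
                    )

    # -- basic accessors ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_events(self) -> int:
        return int(self.y.sum())

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.meta)

    def meta_for(self, name: str) -> PredictorMeta:
        for m in self.meta:
            if m.name == name:
                return m
        raise KeyError(name)

    def has_missing(self) -> bool:
        return any(mask.any() for mask in self.missing.values())

    def both_classes(self) -> bool:
        e = self.n_events
        return 0 < e < self.n

    # -- subsetting --------------------------------------------------------
    def take(self, idx: np.ndarray | Sequence[int]) -> "PatientTable":
        """Row subset/reorder (duplicate indices allowed, for bootstrapping)."""
        idx = np.asarray(idx)
        return PatientTable(
            self.y[idx],
            {k: v[idx] for k, v in self.columns.items()},
            self.meta,
            {k: v[idx] for k, v in self.missing.items()},
        )

    def head(self, n: int) -> "PatientTable":
        return self.take(np.arange(n))

    def with_columns(self, columns: Mapping[str, np.ndarray],
                     missing: Mapping[str, np.ndarray]) -> "PatientTable":
        return PatientTable(self.y, columns, self.meta, missing)

    # -- conversion --------------------------------------------------------
    def to_dataframe(self, outcome_name: str = "outcome") -> pd.DataFrame:
        """Labelled DataFrame view (categorical codes mapped back to labels)."""
        data: dict[str, object] = {outcome_name: self.y.astype(int)}
        for m in self.meta:
            col = self.columns[m.name]
            if m.vtype == "categorical":
                lab = pd.array(
                    [None if np.isnan(v) else m.levels[int(v)] for v in col],
                    dtype="string",
                )
                data[m.name] = lab
            else:
                data[m.name] = col
        return pd.DataFrame(data)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"PatientTable(n={self.n}, events={self.n_events}, "
            f"predictors={len(self.meta)})"
        )


def event_fraction(t: PatientTable) -> float:
    """Observed event fraction (prevalence/incidence), ``events / n``."""
    if t.n == 0:
        raise ValidationError("empty table has no event fraction")
    return t.n_events / t.n


@dataclass(frozen=True)
class StoppingRule:
    """Stopping rule on bootstrap-corrected performance.

    Accrual stops once the corrected calibration slope is at least
    ``slope_min`` *and* the AUC optimism is at most ``optimism_max`` on
    ``consecutive`` consecutive assessments. Thresholds are inclusive.
    """

    name: str = "rule1"
    slope_min: float = 0.9
    optimism_max: float = 0.02
    consecutive: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.slope_min <= 1):
            raise ValidationError("slope_min must be in (0, 1]")
        if self.optimism_max < 0:
            raise ValidationError("optimism_max must be >= 0")
        if self.consecutive < 1:
            raise ValidationError("consecutive must be >= 1")


@dataclass(frozen=True)
class AccrualConfig:
    """Accrual and internal-validation settings for one adaptive run."""

    n_start: int = 100
    n_add: int = 50
    n_max: int = 3000
    B: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_add < 1:
            raise ValidationError("n_add must be >= 1")
        if self.n_max < self.n_start:
            raise ValidationError("n_max must be >= n_start")
        if self.n_start < 2:
            raise ValidationError("n_start must be >= 2")
        if self.B < 1:
            raise ValidationError("B must be >= 1")

    def assessment_sizes(self) -> list[int]:
        return list(range(self.n_start, self.n_max + 1, self.n_add))


# ---------------------------------------------------------------------------
# CSV I/O — comma-separated, UTF-8, '.' decimal, header required; empty cell
# means missing.
# ---------------------------------------------------------------------------

def read_patient_table(
    path: str | Path,
    schema: Sequence[PredictorMeta],
    outcome_name: str = "outcome",
    outcome_labels: tuple[str, str] | None = None,
) -> PatientTable:
    """Read a patient CSV against a declared schema.

    ``outcome_labels``, if given, maps two string labels to (0, 1); otherwise
    the outcome column must already be coded 0/1.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise IOError(f"{path}: empty file") from exc
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise IOError(f"{path}: no data rows")
    if outcome_name not in df.columns:
        raise SchemaError(f"outcome column {outcome_name!r} not in {list(df.columns)}")
    for m in schema:
        if m.name not in df.columns:
            raise SchemaError(f"predictor column {m.name!r} not found in {path.name}")

    raw_y = df[outcome_name].astype(str).str.strip()
    if outcome_labels is not None:
        lab0, lab1 = outcome_labels
        unknown = set(raw_y) - {lab0, lab1}
        if unknown:
            raise ValidationError(f"outcome labels {sorted(unknown)} not in {outcome_labels}")
        y = (raw_y == lab1).to_numpy().astype(np.int8)
    else:
        ok = raw_y.isin(["0", "1"])
        if not ok.all():
            bad = sorted(set(raw_y[~ok]))
            raise ValidationError(f"outcome column must be 0/1, found {bad}")
        y = raw_y.astype(int).to_numpy()

    columns: dict[str, np.ndarray] = {}
    missing: dict[str, np.ndarray] = {}
    for m in schema:
        raw = df[m.name].astype(str).str.strip()
        mask = (raw == "").to_numpy()
        col = np.full(len(df), np.nan)
        obs = ~mask
        if m.vtype == "categorical":
            lut = {lab: float(i) for i, lab in enumerate(m.levels)}
            vals = []
            for v in raw[obs]:
                if v not in lut:
                    raise ValidationError(
                        f"column {m.name!r}: level {v!r} not in {m.levels}"
                    )
                vals.append(lut[v])
            col[obs] = vals
        else:
            try:
                col[obs] = raw[obs].astype(float)
            except ValueError as exc:
                raise ValidationError(f"column {m.name!r}: non-numeric value") from exc
        columns[m.name] = col
        missing[m.name] = mask
    return PatientTable(y, columns, schema, missing)


def write_patient_table(
    t: PatientTable, path: str | Path, outcome_name: str = "outcome"
) -> None:
    """Write a patient CSV; missing cells become empty fields."""
    # Avoid float-formatting drift for integer-valued columns.
    out = {outcome_name: [str(int(v)) for v in t.y]}
    for m in t.meta:
        col = t.columns[m.name]
        mask = t.missing[m.name]
        vals: list[str] = []
        for v, miss in zip(col, mask):
            if miss:
                vals.append("")
            elif m.vtype == "categorical":
                vals.append(m.levels[int(v)])
            elif m.vtype == "binary" or float(v).is_integer():
                vals.append(str(int(v)))
            else:
                vals.append(repr(float(v)))
        out[m.name] = vals
    pd.DataFrame(out).to_csv(path, index=False)
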