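"""Trial tables, dummy encoding, and two-by-two worked-example utilities.

The data model mirrors a two-arm smoking-cessation trial: one row per
participant with the randomized allocation, five baseline covariates (sex,
years smoked, cigarettes smoked weekly, Fagerström nicotine-dependence
category, snuff-use category) and a binary prolonged-abstinence outcome.
``encode_design`` turns a table of records into the predictor matrix the
outcome model consumes: the allocation column first, then reference-level
dummy coding for categorical covariates and standardized continuous
covariates.  Under the default schema (5 dependence levels, 4 snuff levels)
this yields K = 11 predictor columns.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ColumnSpec",
    "TrialSchema",
    "DEFAULT_SCHEMA",
    "TrialRecord",
    "Standardizer",
    "DesignMatrix",
    "TwoByTwoTable",
    "read_trial_csv",
    "write_trial_csv",
    "records_to_frame",
    "frame_to_records",
    "encode_design",
    "decode_design",
    "two_by_two_from_prevalence",
    "odds_ratio",
    "risk_difference_pp",
    "TRIAL_N_TOTAL",
    "TRIAL_N_INTERVENTION",
    "TRIAL_N_CONTROL",
    "TRIAL_N_FOLLOWED_UP",
    "TRIAL_PREV_INTERVENTION",
    "TRIAL_PREV_CONTROL",
]

# Published summary numbers of the motivating trial (used by worked examples
# and as calibration targets for the synthetic generator).
TRIAL_N_TOTAL = 1590
TRIAL_N_INTERVENTION = 827
TRIAL_N_CONTROL = 763
TRIAL_N_FOLLOWED_UP = 1502
TRIAL_PREV_INTERVENTION = 0.259
TRIAL_PREV_CONTROL = 0.146


# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnSpec:
    """One predictor column of the participant table.

    kind is 'binary' (0/1, kept as a single unscaled column), 'continuous'
    (standardized at encoding time) or 'categorical' (ordered integer levels,
    dummy-encoded dropping the lowest, reference, level).
    """

    name: str
    kind: str
    levels: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "continuous", "categorical"):
            raise ValueError(f"unknown column kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical" and len(self.levels) < 2:
            raise ValueError(f"categorical column {self.name!r} needs >= 2 levels")


@dataclass(frozen=True)
class TrialSchema:
    """Ordered predictor columns plus the outcome column name."""

    predictors: tuple[ColumnSpec, ...]
    outcome: str = "outcome"

    def encoded_columns(self) -> list[str]:
        cols: list[str] = []
        for spec in self.predictors:
            if spec.kind == "categorical":
                cols.extend(f"{spec.name}_{lv}" for lv in spec.levels[1:])
            else:
                cols.append(spec.name)
        return cols

    @property
    def k(self) -> int:
        return len(self.encoded_columns())


DEFAULT_SCHEMA = TrialSchema(
    predictors=(
        ColumnSpec("group", "binary"),
        ColumnSpec("sex", "binary"),
        ColumnSpec("years_smoked", "continuous"),
        ColumnSpec("weekly_cigs", "continuous"),
        ColumnSpec("dependence", "categorical", (1, 2, 3, 4, 5)),
        ColumnSpec("snuff", "categorical", (1, 2, 3, 4)),
    )
)


@dataclass(frozen=True)
class TrialRecord:
    """One participant under the default schema.

    group: 1 = offered the intervention, 0 = control (waiting list).
    sex: 1 = female, 0 = male.
    dependence: Fagerström nicotine-dependence category, 1 (low) .. 5 (high).
    snuff: snuff-use category, 1 (none) .. 4 (heavy).
    outcome: 1 = prolonged abstinence reported at follow-up.
    """

    group: int
    sex: int
    years_smoked: float
    weekly_cigs: float
    dependence: int
    snuff: int
    outcome: int

    def __post_init__(self) -> None:
        for name in ("group", "sex", "outcome"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1, got {getattr(self, name)!r}")
        for name in ("years_smoked", "weekly_cigs"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) < 0:
                raise ValueError(f"{name} must be a non-negative number")
        if self.dependence not in DEFAULT_SCHEMA.predictors[4].levels:
            raise ValueError(f"dependence level {self.dependence!r} outside 1..5")
        if self.snuff not in DEFAULT_SCHEMA.predictors[5].levels:
            raise ValueError(f"snuff level {self.snuff!r} outside 1..4")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["group", "sex", "years_smoked", "weekly_cigs", "dependence", "snuff", "outcome"]


def read_trial_csv(path) -> list[TrialRecord]:
    """Read a participant table, validating every row.

    Raises ValueError naming the offending row (1-based data row number) on
    any out-of-range value, and on a missing column up front.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _CSV_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"missing column(s) {missing} in {path}")
        records = []
        for i, row in enumerate(reader, start=1):
            try:
                records.append(
                    TrialRecord(
                        group=int(row["group"]),
                        sex=int(row["sex"]),
                        years_smoked=float(row["years_smoked"]),
                        weekly_cigs=float(row["weekly_cigs"]),
                        dependence=int(row["dependence"]),
                        snuff=int(row["snuff"]),
                        outcome=int(row["outcome"]),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"row {i}: {exc}") from exc
    return records


def write_trial_csv(records: Sequence[TrialRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [r.group, r.sex, repr(float(r.years_smoked)), repr(float(r.weekly_cigs)),
                 r.dependence, r.snuff, r.outcome]
            )


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=_CSV_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[TrialRecord]:
    return [
        TrialRecord(
            group=int(row.group), sex=int(row.sex),
            years_smoked=float(row.years_smoked), weekly_cigs=float(row.weekly_cigs),
            dependence=int(row.dependence), snuff=int(row.snuff), outcome=int(row.outcome),
        )
        for row in frame.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Standardizer:
    """Frozen standardization parameters for the continuous predictors.

    Fitted once on a learning subset and re-applied verbatim to held-out
    rows, so that cross-validation never leaks testing-set moments.
    """

    means: Mapping[str, float]
    sds: Mapping[str, float]

    def transform(self, name: str, values: np.ndarray) -> np.ndarray:
        return (values - self.means[name]) / self.sds[name]

    def inverse(self, name: str, values: np.ndarray) -> np.ndarray:
        return values * self.sds[name] + self.means[name]


@dataclass(frozen=True)
class DesignMatrix:
    """Predictor matrix X (N x K), outcome vector y, and encoding metadata."""

    X: np.ndarray
    y: np.ndarray
    column_names: tuple[str, ...]
    level_maps: Mapping[str, tuple[int, ...]]
    standardizer: Standardizer | None
    schema: TrialSchema

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=list(self.column_names))
        frame[self.schema.outcome] = self.y
        return frame


def _as_frame(data, schema: TrialSchema) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data
    return records_to_frame(list(data))


def encode_design(
    data,
    schema: TrialSchema = DEFAULT_SCHEMA,
    *,
    standardize: bool = True,
    standardizer: Standardizer | None = None,
) -> DesignMatrix:
    """Dummy-encode a trial table into the model's predictor matrix.

    Categorical covariates lose their lowest (reference) level; continuous
    covariates are standardized to mean 0, sd 1.  Pass a previously fitted
    ``standardizer`` to transform held-out rows with learning-set moments
    (the parameters are never re-estimated in that case).
    """
    frame = _as_frame(data, schema)
    if len(frame) == 0:
        raise ValueError("empty record sequence")
    for spec in schema.predictors:
        if spec.name not in frame.columns:
            raise ValueError(f"missing predictor column {spec.name!r}")
    if schema.outcome not in frame.columns:
        raise ValueError(f"missing outcome column {schema.outcome!r}")

    cols: list[np.ndarray] = []
    names: list[str] = []
    level_maps: dict[str, tuple[int, ...]] = {}
    fit_means: dict[str, float] = {}
    fit_sds: dict[str, float] = {}

    for spec in schema.predictors:
        raw = frame[spec.name].to_numpy()
        if spec.kind == "binary":
            vals = raw.astype(float)
            bad = ~np.isin(vals, (0.0, 1.0))
            if bad.any():
                raise ValueError(f"non-binary value in column {spec.name!r}")
            cols.append(vals)
            names.append(spec.name)
        elif spec.kind == "continuous":
            vals = raw.astype(float)
            if standardize:
                if standardizer is not None:
                    vals = standardizer.transform(spec.name, vals)
                else:
                    m, s = float(vals.mean()), float(vals.std(ddof=0))
                    if s == 0.0:
                        raise ValueError(f"constant continuous column {spec.name!r}")
                    fit_means[spec.name], fit_sds[spec.name] = m, s
                    vals = (vals - m) / s
            cols.append(vals)
            names.append(spec.name)
        else:
            vals = raw.astype(int)
            unseen = set(vals.tolist()) - set(spec.levels)
            if unseen:
                raise ValueError(f"unseen level(s) {sorted(unseen)} in column {spec.name!r}")
            level_maps[spec.name] = spec.levels
            for lv in spec.levels[1:]:
                cols.append((vals == lv).astype(float))
                names.append(f"{spec.name}_{lv}")

    y = frame[schema.outcome].to_numpy().astype(int)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("outcome must be binary 0/1")

    if standardize and standardizer is None:
        standardizer = Standardizer(means=fit_means, sds=fit_sds)
    elif not standardize:
        standardizer = None

    X = np.column_stack(cols) if cols else np.empty((len(frame), 0))
    return DesignMatrix(
        X=X, y=y, column_names=tuple(names), level_maps=level_maps,
        standardizer=standardizer, schema=schema,
    )


def decode_design(design: DesignMatrix) -> pd.DataFrame:
    """Invert the encoding back to original covariate values (round trip)."""
    out: dict[str, np.ndarray] = {}
    names = list(design.column_names)
    for spec in design.schema.predictors:
        if spec.kind == "binary":
            out[spec.name] = design.X[:, names.index(spec.name)].astype(int)
        elif spec.kind == "continuous":
            vals = design.X[:, names.index(spec.name)]
            if design.standardizer is not None and spec.name in design.standardizer.means:
                vals = design.standardizer.inverse(spec.name, vals)
            out[spec.name] = vals
        else:
            levels = design.level_maps[spec.name]
            decoded = np.full(design.n, levels[0])
            for lv in levels[1:]:
                mask = design.X[:, names.index(f"{spec.name}_{lv}")] == 1.0
                decoded[mask] = lv
            out[spec.name] = decoded
    out[design.schema.outcome] = design.y
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Two-by-two worked examples
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoByTwoTable:
    """Outcome-by-arm counts: a/b = events/non-events in arm 1, c/d in arm 0."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def two_by_two_from_prevalence(
    n_arm1: int, n_arm0: int, prev1: float, prev0: float
) -> TwoByTwoTable:
    """Reconstruct event counts from arm sizes and printed prevalences."""
    for label, p in (("prev1", prev1), ("prev0", prev0)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{label} must lie in [0, 1], got {p}")
    if n_arm1 < 0 or n_arm0 < 0:
        raise ValueError("arm sizes must be non-negative")
    a = _round_half_away(n_arm1 * prev1)
    c = _round_half_away(n_arm0 * prev0)
    return TwoByTwoTable(a=a, b=n_arm1 - a, c=c, d=n_arm0 - c)


def odds_ratio(table: TwoByTwoTable) -> float:
    """Cross-product odds ratio (a/b)/(c/d); zero cells are an error."""
    if 0 in (table.a, table.b, table.c, table.d):
        raise ValueError("zero cell: odds ratio undefined (no continuity correction applied)")
    return (table.a / table.b) / (table.c / table.d)


def risk_difference_pp(table: TwoByTwoTable) -> float:
    """Risk difference between arms in percentage points."""
    n1, n0 = table.a + table.b, table.c + table.d
    if n1 == 0 or n0 == 0:
        raise ValueError("empty arm")
    return 100.0 * (table.a / n1 - table.c / n0)
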