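"""Tabular data model shared by every stage of the balancing pipeline.

A :class:`LabeledTable` is a dense feature matrix with a binary target and a
:class:`FeatureSchema` describing which columns are 0/1 indicators and which
are continuous measurements (hormone levels, age).  The schema distinction
matters downstream: standardization z-scores continuous columns only, and the
distance-based steps (k-NN queries, k-means) operate on the standardized
matrix.

Conventions
-----------
* Labels are coded ``0`` = majority / negative ("no") and ``1`` = minority /
  positive ("yes").
* CSV files are RFC-4180 with a mandatory header row, UTF-8, '.' decimal.
  A schema may be supplied as a JSON sidecar; otherwise it is inferred
  (columns whose non-missing values all lie in {0, 1} are tagged binary).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

BINARY = "binary"
CONTINUOUS = "continuous"

#: Column layout of the reference thyroid table: 21 features + target.
#: "Unnamed:22" is the junk all-null column of the source file; clean() drops it.
THYROID_BINARY_FEATURES = (
    "Sex",
    "on_thyroxine",
    "query_on_thyroxine",
    "on_antithyroid_medication",
    "sick",
    "pregnant",
    "thyroid_surgery",
    "I131_treatment",
    "query_hypothyroid",
    "query_hyperthyroid",
    "lithium",
    "goitre",
    "tumor",
    "Unnamed:22",
    "psych",
)
THYROID_CONTINUOUS_FEATURES = (
    "Age",
    "TSH",
    "T3_measured",
    "TT4_measured",
    "T4U_measured",
    "FTI_measured",
)
THYROID_TARGET = "Outlier_label"


class TableError(ValueError):
    """Raised for malformed tables or CSV files."""


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature names with per-feature kind tags and target coding."""

    feature_names: tuple[str, ...]
    feature_kinds: tuple[str, ...]
    target_name: str = THYROID_TARGET
    positive_label: str = "yes"
    negative_label: str = "no"

    def __post_init__(self) -> None:
        if len(self.feature_names) != len(self.feature_kinds):
            raise TableError("feature_names and feature_kinds length mismatch")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise TableError("feature names must be unique")
        if self.target_name in self.feature_names:
            raise TableError("target_name must not be among feature_names")
        bad = [k for k in self.feature_kinds if k not in (BINARY, CONTINUOUS)]
        if bad:
            raise TableError(f"unknown feature kinds: {bad}")

    @property
    def d(self) -> int:
        return len(self.feature_names)

    def kind_of(self, name: str) -> str:
        return self.feature_kinds[self.feature_names.index(name)]

    @property
    def continuous_mask(self) -> np.ndarray:
        return np.array([k == CONTINUOUS for k in self.feature_kinds])

    @property
    def binary_mask(self) -> np.ndarray:
        return ~self.continuous_mask

    def drop(self, names: Iterable[str]) -> "FeatureSchema":
        names = set(names)
        keep = [(n, k) for n, k in zip(self.feature_names, self.feature_kinds) if n not in names]
        return replace(
            self,
            feature_names=tuple(n for n, _ in keep),
            feature_kinds=tuple(k for _, k in keep),
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "features": [
                {"name": n, "kind": k}
                for n, k in zip(self.feature_names, self.feature_kinds)
            ],
            "target": self.target_name,
            "positive_label": self.positive_label,
            "negative_label": self.negative_label,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureSchema":
        payload = json.loads(Path(path).read_text())
        return cls(
            feature_names=tuple(f["name"] for f in payload["features"]),
            feature_kinds=tuple(f["kind"] for f in payload["features"]),
            target_name=payload["target"],
            positive_label=payload.get("positive_label", "yes"),
            negative_label=payload.get("negative_label", "no"),
        )


def thyroid_schema() -> FeatureSchema:
    """The 21-feature reference schema of the thyroid table."""
    # Table order: Age, then the indicator block, then the hormone block.
    ordered = (
        ("Age", CONTINUOUS),
        ("Sex", BINARY),
        ("on_thyroxine", BINARY),
        ("query_on_thyroxine", BINARY),
        ("on_antithyroid_medication", BINARY),
        ("sick", BINARY),
        ("pregnant", BINARY),
        ("thyroid_surgery", BINARY),
        ("I131_treatment", BINARY),
        ("query_hypothyroid", BINARY),
        ("query_hyperthyroid", BINARY),
        ("lithium", BINARY),
        ("goitre", BINARY),
        ("tumor", BINARY),
        ("Unnamed:22", BINARY),
        ("psych", BINARY),
        ("TSH", CONTINUOUS),
        ("T3_measured", CONTINUOUS),
        ("TT4_measured", CONTINUOUS),
        ("T4U_measured", CONTINUOUS),
        ("FTI_measured", CONTINUOUS),
    )
    return FeatureSchema(
        feature_names=tuple(n for n, _ in ordered),
        feature_kinds=tuple(k for _, k in ordered),
    )


@dataclass(frozen=True)
class LabeledTable:
    """Feature matrix ``X`` (n x d) with binary labels ``y`` and a schema."""

    X: np.ndarray
    y: np.ndarray
    schema: FeatureSchema

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=int)
        if X.ndim != 2:
            raise TableError("X must be 2-D")
        if y.ndim != 1 or y.shape[0] != X.shape[0]:
            raise TableError("y length must equal number of rows of X")
        if X.shape[1] != self.schema.d:
            raise TableError(
                f"X has {X.shape[1]} columns but schema defines {self.schema.d} features"
            )
        if y.size and not np.isin(y, (0, 1)).all():
            raise TableError("labels must be 0/1")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def class_counts(self) -> tuple[int, int]:
        """(count of y=0, count of y=1)."""
        return int(np.sum(self.y == 0)), int(np.sum(self.y == 1))

    def subset(self, idx: np.ndarray | Sequence[int]) -> "LabeledTable":
        idx = np.asarray(idx)
        return LabeledTable(self.X[idx], self.y[idx], self.schema)

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.schema.feature_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.schema.feature_names))
        df[self.schema.target_name] = np.where(
            self.y == 1, self.schema.positive_label, self.schema.negative_label
        )
        return df

    def equals(self, other: "LabeledTable") -> bool:
        return (
            self.schema == other.schema
            and np.array_equal(self.X, other.X, equal_nan=True)
            and np.array_equal(self.y, other.y)
        )


@dataclass(frozen=True)
class SplitPair:
    """A train/test partition; resamplers accept only ``train``."""

    train: LabeledTable
    test: LabeledTable
    ratio: float
    seed: int
    stratified: bool
    train_indices: np.ndarray = field(repr=False, default=None)
    test_indices: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _infer_schema(df: pd.DataFrame, target_name: str | None) -> FeatureSchema:
    if target_name is None:
        target_name = THYROID_TARGET if THYROID_TARGET in df.columns else df.columns[-1]
    names, kinds = [], []
    for col in df.columns:
        if col == target_name:
            continue
        vals = pd.to_numeric(df[col], errors="coerce").dropna().unique()
        kind = BINARY if len(vals) <= 2 and np.isin(vals, (0.0, 1.0)).all() else CONTINUOUS
        names.append(col)
        kinds.append(kind)
    # positive label: 'yes' if present among target values, else the value mapping to 1
    tvals = set(str(v).strip().lower() for v in df[target_name].dropna().unique())
    pos, neg = "yes", "no"
    if not ({"yes", "no"} & tvals):
        pos, neg = "1", "0"
    return FeatureSchema(tuple(names), tuple(kinds), target_name, pos, neg)


def load_csv(path: str | Path, schema: FeatureSchema | None = None) -> LabeledTable:
    """Read a labeled CSV.  Row order is preserved.

    Rows with a missing target value are dropped (with a warning); missing
    feature cells survive to be handled by :func:`clean`.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if schema is None:
        schema = _infer_schema(df, None)
    if schema.target_name not in df.columns:
        raise TableError(f"missing target column {schema.target_name!r} in {path}")
    missing_cols = [c for c in schema.feature_names if c not in df.columns]
    if missing_cols:
        raise TableError(f"missing feature columns {missing_cols} in {path}")

    tcol = df[schema.target_name]
    keep = tcol.notna()
    if not keep.all():
        warnings.warn(
            f"dropped {int((~keep).sum())} rows with missing target", stacklevel=2
        )
        df = df.loc[keep]
        tcol = tcol.loc[keep]

    cols = []
    for name, kind in zip(schema.feature_names, schema.feature_kinds):
        raw = df[name]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & raw.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TableError(
                f"non-numeric cell in column {name!r} at row {row}: {raw.iloc[row]!r}"
            )
        cols.append(num.to_numpy(dtype=float))
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))

    tnorm = tcol.astype(str).str.strip().str.lower()
    y = (tnorm == schema.positive_label.lower()).to_numpy().astype(int)
    return LabeledTable(X, y, schema)


def write_csv(table: LabeledTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------

def clean(
    table: LabeledTable,
    winsorize: tuple[float, float] | None = None,
) -> LabeledTable:
    """Drop all-null columns, impute missing cells, optionally winsorize.

    * Columns that are entirely missing (the reference file's junk column) are
      removed from matrix and schema.
    * Remaining missing cells are imputed by the column median (continuous) or
      mode (binary; ties go to the smaller value).
    * ``winsorize=(lo, hi)`` clips continuous columns at those quantiles
      (computed on non-missing values); default off.
    """
    if table.n == 0:
        raise TableError("clean() on an empty table")
    X = table.X.copy()
    schema = table.schema

    all_null = np.isnan(X).all(axis=0)
    if all_null.any():
        dropped = [n for n, m in zip(schema.feature_names, all_null) if m]
        schema = schema.drop(dropped)
        X = X[:, ~all_null]

    kinds = schema.feature_kinds
    for j in range(X.shape[1]):
        col = X[:, j]
        miss = np.isnan(col)
        if miss.any():
            obs = col[~miss]
            if obs.size == 0:
                raise TableError("column became all-missing during clean")
            if kinds[j] == CONTINUOUS:
                fill = float(np.median(obs))
            else:
                ones = int(np.sum(obs == 1))
                zeros = obs.size - ones
                fill = 1.0 if ones > zeros else 0.0  # tie -> smaller value
            col[miss] = fill
        if winsorize is not None and kinds[j] == CONTINUOUS:
            lo, hi = np.quantile(col, winsorize)
            X[:, j] = np.clip(col, lo, hi)
    return LabeledTable(X, table.y.copy(), schema)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclass
class Standardizer:
    """Z-scoring of continuous columns, fitted on the training split only.

    Population denominator ``n``; binary columns pass through; a zero-variance
    column gets scale 1 so its values map to 0.
    """

    location: np.ndarray | None = None
    scale: np.ndarray | None = None
    _mask: np.ndarray | None = None

    def fit(self, train: LabeledTable) -> "Standardizer":
        mask = train.schema.continuous_mask
        loc = np.zeros(train.d)
        scale = np.ones(train.d)
        if mask.any():
            sub = train.X[:, mask]
            loc[mask] = sub.mean(axis=0)
            sd = sub.std(axis=0)  # population (ddof=0)
            sd[sd == 0.0] = 1.0
            scale[mask] = sd
        self.location, self.scale, self._mask = loc, scale, mask
        return self

    def transform(self, table: LabeledTable) -> LabeledTable:
        if self.location is None:
            raise TableError("Standardizer not fitted")
        X = (table.X - self.location) / self.scale
        return LabeledTable(X, table.y.copy(), table.schema)

    def inverse_transform(self, table: LabeledTable) -> LabeledTable:
        if self.location is None:
            raise TableError("Standardizer not fitted")
        X = table.X * self.scale + self.location
        return LabeledTable(X, table.y.copy(), table.schema)


def standardize(
    train: LabeledTable, *apply_to: LabeledTable
) -> tuple[list[LabeledTable], Standardizer]:
    """Fit on ``train``, transform train plus any further tables."""
    sc = Standardizer().fit(train)
    return [sc.transform(t) for t in (train, *apply_to)], sc


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split(
    table: LabeledTable,
    ratio: float = 0.8,
    seed: int = 0,
    stratified: bool = False,
) -> SplitPair:
    """Random train/test partition; train size is ``floor(ratio * n)``.

    The permutation is driven solely by ``seed``.  Stratified mode applies the
    same floor rule to each class independently.
    """
    if not 0.0 < ratio < 1.0:
        raise TableError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if stratified:
        tr_parts, te_parts = [], []
        for cls in (0, 1):
            idx = np.flatnonzero(table.y == cls)
            perm = rng.permutation(idx)
            cut = int(np.floor(ratio * idx.size))
            tr_parts.append(perm[:cut])
            te_parts.append(perm[cut:])
        tr = np.sort(np.concatenate(tr_parts))
        te = np.sort(np.concatenate(te_parts))
    else:
        perm = rng.permutation(table.n)
        cut = int(np.floor(ratio * table.n))
        tr, te = np.sort(perm[:cut]), np.sort(perm[cut:])
    train, test = table.subset(tr), table.subset(te)
    for part, label in ((train, "train"), (test, "test")):
        c0, c1 = part.class_counts
        if part.n and (c0 == 0 or c1 == 0):
            warnings.warn(f"a class is absent from the {label} split", stacklevel=2)
    return SplitPair(train, test, ratio, seed, stratified, tr, te)
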