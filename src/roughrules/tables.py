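"""Decision tables: the universal learning input.

A decision table is a finite grid of objects (rows) by features (columns)
plus one designated decision column holding class labels.  Features are
either continuous (finite floats) or discrete (string levels).  All
learning operations downstream require discrete features; continuous
features are converted with equal-frequency discretization whose cut
points are fitted on training data and re-applied to held-out data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "DecisionTable",
    "DiscretizationMap",
    "read_decision_table",
    "write_decision_table",
    "fit_equal_frequency",
    "apply_discretization",
    "SEMANTIC_BIN_LABELS",
]

CONTINUOUS = "continuous"
DISCRETE = "discrete"

#: Optional human-readable bin aliases, keyed by bin count.
SEMANTIC_BIN_LABELS = {
    2: ("low", "high"),
    3: ("low", "medium", "high"),
}


class DataError(ValueError):
    """Malformed input data (duplicates, missing cells, empty table)."""


class ConfigError(ValueError):
    """Invalid configuration (unknown column, bad parameter)."""


@dataclass
class DecisionTable:
    """Objects x features grid with one decision column.

    ``values`` is row-major: ``values[i][j]`` is the value of feature
    ``feature_names[j]`` for object ``object_ids[i]``.  Continuous cells
    are floats, discrete cells are strings.  ``row_weights`` carries
    equivalence-class cardinalities for generalized tables and defaults
    to 1 per row.
    """

    object_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: tuple[tuple, ...]
    decision_name: str
    decisions: tuple[str, ...]
    value_kind: tuple[str, ...]
    row_weights: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.object_ids) == 0:
            raise DataError("decision table must contain at least one object")
        if len(self.feature_names) == 0:
            raise DataError("decision table must contain at least one feature")
        if len(set(self.object_ids)) != len(self.object_ids):
            raise DataError("duplicate object ids")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise DataError("duplicate feature names")
        if self.decision_name in self.feature_names:
            raise DataError(
                f"decision column {self.decision_name!r} repeats a feature name"
            )
        if len(self.decisions) != len(self.object_ids):
            raise DataError("decisions do not align with objects")
        if len(self.value_kind) != len(self.feature_names):
            raise DataError("value_kind does not align with features")
        for row in self.values:
            if len(row) != len(self.feature_names):
                raise DataError("ragged row in decision table")
            for cell in row:
                if cell is None or (isinstance(cell, float) and math.isnan(cell)):
                    raise DataError("missing cell values are not supported")
        if not self.row_weights:
            self.row_weights = tuple(1 for _ in self.object_ids)
        elif len(self.row_weights) != len(self.object_ids):
            raise DataError("row_weights do not align with objects")

    # -- basic accessors ------------------------------------------------

    @property
    def n_objects(self) -> int:
        return len(self.object_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def classes(self) -> tuple[str, ...]:
        """Decision labels in order of first appearance."""
        seen: dict[str, None] = {}
        for d in self.decisions:
            seen.setdefault(d, None)
        return tuple(seen)

    def feature_index(self, name: str) -> int:
        try:
            return self.feature_names.index(name)
        except ValueError:
            raise ConfigError(f"unknown feature {name!r}") from None

    def column(self, name: str) -> tuple:
        j = self.feature_index(name)
        return tuple(row[j] for row in self.values)

    def is_discrete(self) -> bool:
        return all(k == DISCRETE for k in self.value_kind)

    def require_discrete(self) -> None:
        if not self.is_discrete():
            bad = [
                f for f, k in zip(self.feature_names, self.value_kind) if k != DISCRETE
            ]
            raise ConfigError(f"operation requires discrete features; continuous: {bad}")

    def subset_objects(self, indices) -> "DecisionTable":
        """New table restricted to the given row indices (order kept)."""
        idx = list(indices)
        return replace(
            self,
            object_ids=tuple(self.object_ids[i] for i in idx),
            values=tuple(self.values[i] for i in idx),
            decisions=tuple(self.decisions[i] for i in idx),
            row_weights=tuple(self.row_weights[i] for i in idx),
        )

    def to_dataframe(self, include_ids: bool = True) -> pd.DataFrame:
        data = {}
        if include_ids:
            data["object"] = list(self.object_ids)
        for j, name in enumerate(self.feature_names):
            data[name] = [row[j] for row in self.values]
        data[self.decision_name] = list(self.decisions)
        return pd.DataFrame(data)


@dataclass(frozen=True)
class DiscretizationMap:
    """Per-feature equal-frequency cut points fitted on training data.

    ``cuts[f]`` is a strictly increasing tuple; a value v falls in bin
    ``#{c in cuts[f] : v > c}`` so out-of-range values clamp to the
    extreme bins.  Discrete features are absent from ``cuts`` and pass
    through unchanged.
    """

    cuts: dict[str, tuple[float, ...]]
    bin_count: int
    labels: tuple[str, ...] | None = None

    def bin_labels(self, feature: str) -> tuple[str, ...]:
        n = len(self.cuts[feature]) + 1
        if self.labels is not None and len(self.labels) == n:
            return self.labels
        return tuple(str(i + 1) for i in range(n))

    def bin_of(self, feature: str, value: float) -> str:
        cuts = self.cuts[feature]
        k = sum(1 for c in cuts if value > c)
        return self.bin_labels(feature)[k]


def read_decision_table(
    path,
    decision_column: str = "last",
    delimiter: str = ",",
    id_column: bool = False,
) -> DecisionTable:
    """Load a delimited text file with a header row into a DecisionTable.

    Columns whose every cell parses as a number are typed continuous;
    everything else is discrete.  ``decision_column="last"`` designates
    the final column.  With ``id_column`` the first column supplies
    object ids, otherwise ids are ``"1".."n"``.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise DataError(f"{path}: empty table")
    if id_column:
        ids = tuple(df.iloc[:, 0].astype(str))
        df = df.iloc[:, 1:]
    else:
        ids = tuple(str(i + 1) for i in range(len(df)))
    columns = list(df.columns)
    if decision_column == "last":
        decision_name = columns[-1]
    else:
        if decision_column not in columns:
            raise ConfigError(f"decision column {decision_column!r} not in header")
        decision_name = decision_column
    feature_names = tuple(c for c in columns if c != decision_name)
    if not feature_names:
        raise DataError("no feature columns besides the decision")

    for c in columns:
        if (df[c].astype(str).str.strip() == "").any():
            raise DataError(f"missing cell in column {c!r}")

    kinds = []
    typed: dict[str, list] = {}
    for f in feature_names:
        raw = list(df[f].astype(str))
        try:
            typed[f] = [float(v) for v in raw]
            kinds.append(CONTINUOUS)
        except ValueError:
            typed[f] = raw
            kinds.append(DISCRETE)
    rows = tuple(
        tuple(typed[f][i] for f in feature_names) for i in range(len(df))
    )
    return DecisionTable(
        object_ids=ids,
        feature_names=feature_names,
        values=rows,
        decision_name=decision_name,
        decisions=tuple(df[decision_name].astype(str)),
        value_kind=tuple(kinds),
    )


def write_decision_table(
    dt: DecisionTable, path, delimiter: str = ",", include_ids: bool = False
) -> None:
    df = dt.to_dataframe(include_ids=include_ids)
    for f, kind in zip(dt.feature_names, dt.value_kind):
        if kind == CONTINUOUS:
            df[f] = df[f].map(lambda v: repr(float(v)))
    df.to_csv(path, sep=delimiter, index=False)


def fit_equal_frequency(
    dt: DecisionTable,
    bins: int,
    labels: tuple[str, ...] | None = None,
    semantic_labels: bool = False,
) -> DiscretizationMap:
    """Fit equal-frequency cut points for every continuous feature.

    Cuts sit at the empirical values of rank ``ceil(k*m/bins)`` for
    k = 1..bins-1 so that fit-then-apply yields bins whose occupancies
    differ by at most one when values are distinct.  Tied quantiles
    merge bins (a value maps to exactly one bin); features with fewer
    distinct values than bins collapse with a warning.
    """
    if bins < 2:
        raise ConfigError("bins must be >= 2")
    if labels is None and semantic_labels and bins in SEMANTIC_BIN_LABELS:
        labels = SEMANTIC_BIN_LABELS[bins]
    cuts: dict[str, tuple[float, ...]] = {}
    for f, kind in zip(dt.feature_names, dt.value_kind):
        if kind != CONTINUOUS:
            continue
        vals = sorted(float(v) for v in dt.column(f))
        m = len(vals)
        raw = [vals[math.ceil(k * m / bins) - 1] for k in range(1, bins)]
        vmax = vals[-1]
        keep: list[float] = []
        for c in raw:
            if c < vmax and (not keep or c > keep[-1]):
                keep.append(c)
        if len(keep) + 1 < bins:
            warnings.warn(
                f"feature {f!r}: only {len(keep) + 1} equal-frequency bins "
                f"possible (requested {bins})",
                stacklevel=2,
            )
        cuts[f] = tuple(keep)
    return DiscretizationMap(cuts=cuts, bin_count=bins, labels=labels)


def apply_discretization(dt: DecisionTable, dmap: DiscretizationMap) -> DecisionTable:
    """Apply fitted cuts, returning an all-discrete table.

    Out-of-range values clamp to the extreme bins; discrete features are
    untouched.  Unknown features in the map raise a configuration error.
    """
    unknown = set(dmap.cuts) - set(dt.feature_names)
    if unknown:
        raise ConfigError(f"discretization map names unknown features: {sorted(unknown)}")
    continuous = {
        f for f, k in zip(dt.feature_names, dt.value_kind) if k == CONTINUOUS
    }
    uncovered = continuous - set(dmap.cuts)
    if uncovered:
        raise ConfigError(f"map does not cover continuous features: {sorted(uncovered)}")
    new_rows = []
    for row in dt.values:
        new_row = []
        for f, cell in zip(dt.feature_names, row):
            if f in dmap.cuts:
                new_row.append(dmap.bin_of(f, float(cell)))
            else:
                new_row.append(cell)
        new_rows.append(tuple(new_row))
    return replace(
        dt,
        values=tuple(new_rows),
        value_kind=tuple(DISCRETE for _ in dt.feature_names),
    )
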