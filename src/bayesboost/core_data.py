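"""Typed tabular datasets and the plumbing shared by every pipeline stage.

A :class:`TabularDataset` is a pandas frame plus a :class:`Schema` that
declares, for every column, whether it is categorical (with an explicit level
set) or numeric, and which columns play the *target* (binary disease outcome,
encoded ``"0"``/``"1"``) and *protected attribute* (discrete variable whose
levels define the population groups audited for under-representation) roles.

The module also provides stratified splitting, quantile discretization with an
invertible :class:`BinningMap` (the network stages operate on fully discrete
data), and the bounded distribution-distance used to rank attributes:
total variation for categorical columns, the two-sample Kolmogorov–Smirnov
statistic for numeric ones — both live in ``[0, 1]`` so they are comparable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

logger = logging.getLogger("bayesboost")

CATEGORICAL = "categorical"
NUMERIC = "numeric"

#: role tags a dataset may carry through the pipeline
ROLES = ("ground_truth", "biased", "uncertain", "boosted", "baseline-output")


class SchemaError(ValueError):
    """A value or declaration violates the dataset schema."""


@dataclass(frozen=True)
class Variable:
    """One column declaration: a name, a kind, and levels or a numeric range."""

    name: str
    kind: str
    levels: tuple[str, ...] | None = None
    bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in (CATEGORICAL, NUMERIC):
            raise SchemaError(f"unknown kind {self.kind!r} for variable {self.name!r}")
        if self.kind == CATEGORICAL:
            if not self.levels or len(set(self.levels)) != len(self.levels):
                raise SchemaError(f"categorical variable {self.name!r} needs unique levels")
        elif self.levels is not None:
            raise SchemaError(f"numeric variable {self.name!r} must not declare levels")


@dataclass(frozen=True)
class Schema:
    """Ordered variable declarations plus target / protected designations.

    Invariants: names unique; the target is categorical with levels exactly
    ``("0", "1")``; the protected attribute is categorical with >= 2 levels.
    """

    variables: tuple[Variable, ...]
    target_name: str
    protected_name: str

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SchemaError("variable names must be unique")
        tgt = self.var(self.target_name)
        if tgt.kind != CATEGORICAL or set(tgt.levels) != {"0", "1"}:
            raise SchemaError("target must be categorical with levels {'0','1'}")
        prot = self.var(self.protected_name)
        if prot.kind != CATEGORICAL or len(prot.levels) < 2:
            raise SchemaError("protected attribute must be categorical with >=2 levels")

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def var(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise SchemaError(f"unknown variable {name!r}")

    @property
    def numeric_names(self) -> list[str]:
        return [v.name for v in self.variables if v.kind == NUMERIC]

    @property
    def categorical_names(self) -> list[str]:
        return [v.name for v in self.variables if v.kind == CATEGORICAL]

    @property
    def feature_names(self) -> list[str]:
        return [v.name for v in self.variables if v.name != self.target_name]

    def replace_variable(self, name: str, new: Variable) -> "Schema":
        variables = tuple(new if v.name == name else v for v in self.variables)
        return replace(self, variables=variables)

    # -- YAML round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        out = []
        for v in self.variables:
            d: dict = {"name": v.name, "kind": v.kind}
            if v.levels is not None:
                d["levels"] = list(v.levels)
            if v.bounds is not None:
                d["bounds"] = list(v.bounds)
            out.append(d)
        return {"variables": out, "target": self.target_name, "protected": self.protected_name}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Schema":
        variables = tuple(
            Variable(
                name=v["name"],
                kind=v["kind"],
                levels=tuple(str(x) for x in v["levels"]) if v.get("levels") else None,
                bounds=tuple(v["bounds"]) if v.get("bounds") else None,
            )
            for v in d["variables"]
        )
        return cls(variables=variables, target_name=d["target"], protected_name=d["protected"])

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Schema":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class TabularDataset:
    """Rows conforming to a :class:`Schema`, with a pipeline role tag.

    ``provenance`` optionally tags each row ``original`` or ``synthetic`` —
    boosted datasets carry it so the merge contract (original rows preserved)
    is checkable.
    """

    schema: Schema
    frame: pd.DataFrame
    role: str = "ground_truth"
    provenance: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise SchemaError(f"unknown role {self.role!r}")
        if len(self.frame) == 0:
            raise SchemaError("dataset must have at least one row")
        missing = set(self.schema.names) - set(self.frame.columns)
        if missing:
            raise SchemaError(f"frame is missing columns {sorted(missing)}")
        self.frame = self.frame[self.schema.names].reset_index(drop=True)
        for v in self.schema.variables:
            col = self.frame[v.name]
            if v.kind == CATEGORICAL:
                vals = col.astype(str)
                bad = set(vals.unique()) - set(v.levels)
                if bad:
                    raise SchemaError(
                        f"column {v.name!r} contains undeclared level(s) {sorted(bad)!r}"
                    )
                self.frame[v.name] = vals
            else:
                self.frame[v.name] = pd.to_numeric(col)
        if self.frame[self.schema.target_name].isna().any():
            raise SchemaError("target column contains missing values")
        if self.provenance is not None:
            self.provenance = np.asarray(self.provenance, dtype=object)
            if len(self.provenance) != len(self.frame):
                raise SchemaError("provenance length mismatch")

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def labels(self) -> np.ndarray:
        """Target column as an int array in {0, 1}."""
        return self.frame[self.schema.target_name].astype(int).to_numpy()

    def subset(self, index: Sequence[int] | np.ndarray, role: str | None = None) -> "TabularDataset":
        idx = np.asarray(index)
        prov = self.provenance[idx] if self.provenance is not None else None
        return TabularDataset(
            schema=self.schema,
            frame=self.frame.iloc[idx].reset_index(drop=True),
            role=role or self.role,
            provenance=prov,
        )

    def with_role(self, role: str) -> "TabularDataset":
        return TabularDataset(self.schema, self.frame.copy(), role, self.provenance)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_csv(path: str | Path, schema: Schema, role: str = "ground_truth") -> TabularDataset:
    """Load a CSV whose header matches the schema; validates levels and types.

    Raises :class:`SchemaError` naming the offending column/value on an
    undeclared categorical level, and on missing target values.
    """
    frame = pd.read_csv(path, dtype=str)
    missing = set(schema.names) - set(frame.columns)
    if missing:
        raise SchemaError(f"CSV {path} lacks columns {sorted(missing)}")
    if frame[schema.target_name].isna().any():
        raise SchemaError(f"CSV {path}: target {schema.target_name!r} has missing values")
    provenance = None
    if "provenance" in frame.columns:
        provenance = frame["provenance"].to_numpy(dtype=object)
    return TabularDataset(schema=schema, frame=frame, role=role, provenance=provenance)


def write_csv(dataset: TabularDataset, path: str | Path, include_provenance: bool = False) -> None:
    """Write a dataset as UTF-8 comma-separated CSV in schema column order."""
    frame = dataset.frame.copy()
    if include_provenance and dataset.provenance is not None:
        frame["provenance"] = dataset.provenance
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Stratified splitting
# ---------------------------------------------------------------------------

def stratified_split(
    dataset: TabularDataset,
    strata_variable: str,
    fraction: float,
    seed: int,
    return_indices: bool = False,
):
    """Split so each stratum contributes round(fraction * count) rows to part A.

    Rounding is half-up per stratum; the remainder goes to part B. The split is
    a partition of the rows and is deterministic under a fixed seed. With
    ``return_indices`` the source row positions of both parts are appended to
    the return tuple (used for leakage bookkeeping).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    col = dataset.frame[strata_variable].astype(str).to_numpy()
    a_idx: list[np.ndarray] = []
    b_idx: list[np.ndarray] = []
    levels = sorted(pd.unique(col))
    for level in levels:
        members = np.flatnonzero(col == level)
        if members.size == 0:  # pragma: no cover - cannot occur via unique()
            warnings.warn(f"stratum {level!r} empty; skipped")
            continue
        take = int(np.floor(fraction * members.size + 0.5))
        perm = rng.permutation(members)
        a_idx.append(perm[:take])
        b_idx.append(perm[take:])
    part_a = np.sort(np.concatenate(a_idx)) if a_idx else np.array([], dtype=int)
    part_b = np.sort(np.concatenate(b_idx)) if b_idx else np.array([], dtype=int)
    if return_indices:
        return dataset.subset(part_a), dataset.subset(part_b), part_a, part_b
    return dataset.subset(part_a), dataset.subset(part_b)


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Bin:
    label: str
    low: float
    high: float


@dataclass
class BinningMap:
    """Per numeric variable: ordered bins with their real intervals.

    Cut points are strictly increasing; bins cover the observed range. The
    last bin is closed on the right, the others half-open ``[low, high)``.
    """

    bins: dict[str, list[Bin]] = field(default_factory=dict)

    def cutpoints(self, name: str) -> np.ndarray:
        return np.array([b.high for b in self.bins[name][:-1]])

    def assign(self, name: str, values: np.ndarray) -> np.ndarray:
        """Map numeric values to bin labels (values outside the range clip)."""
        idx = np.searchsorted(self.cutpoints(name), values, side="right")
        labels = np.array([b.label for b in self.bins[name]], dtype=object)
        return labels[np.clip(idx, 0, len(labels) - 1)]

    def interval(self, name: str, label: str) -> tuple[float, float]:
        for b in self.bins[name]:
            if b.label == label:
                return (b.low, b.high)
        raise KeyError(f"unknown bin label {label!r} for {name!r}")


def _bin_label(low: float, high: float) -> str:
    return f"[{low:.6g},{high:.6g})"


def discretize(dataset: TabularDataset, n_bins: int = 5) -> tuple[TabularDataset, BinningMap]:
    """Replace each numeric variable by quantile-based bins.

    Returns the discrete dataset together with the :class:`BinningMap` needed
    to invert. A constant numeric column collapses to a single bin with a
    warning. Already-categorical columns pass through unchanged.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    frame = dataset.frame.copy()
    bmap = BinningMap()
    variables = []
    for v in dataset.schema.variables:
        if v.kind == CATEGORICAL:
            variables.append(v)
            continue
        values = frame[v.name].to_numpy(dtype=float)
        qs = np.quantile(values, np.linspace(0, 1, n_bins + 1))
        edges = np.unique(qs)
        if len(edges) == 1:
            warnings.warn(f"numeric column {v.name!r} is constant; single bin used")
            edges = np.array([edges[0], edges[0] + 1e-9])
        bins = [
            Bin(_bin_label(lo, hi), float(lo), float(hi))
            for lo, hi in zip(edges[:-1], edges[1:])
        ]
        bmap.bins[v.name] = bins
        frame[v.name] = bmap.assign(v.name, values)
        variables.append(Variable(v.name, CATEGORICAL, tuple(b.label for b in bins)))
    schema = Schema(tuple(variables), dataset.schema.target_name, dataset.schema.protected_name)
    return TabularDataset(schema, frame, dataset.role, dataset.provenance), bmap


def undiscretize(
    dataset: TabularDataset,
    binning: BinningMap,
    seed: int,
    numeric_schema: Schema | None = None,
) -> TabularDataset:
    """Invert :func:`discretize` by drawing uniformly within each cell's bin.

    ``numeric_schema`` restores the original (numeric) variable declarations;
    if omitted, one is reconstructed from the binning map's ranges.
    """
    rng = np.random.default_rng(seed)
    frame = dataset.frame.copy()
    variables = []
    for v in dataset.schema.variables:
        if v.name not in binning.bins:
            variables.append(v)
            continue
        labels = frame[v.name].astype(str).to_numpy()
        known = {b.label for b in binning.bins[v.name]}
        bad = set(labels) - known
        if bad:
            raise KeyError(f"unknown bin label(s) {sorted(bad)!r} for {v.name!r}")
        lows = np.empty(len(labels))
        highs = np.empty(len(labels))
        for b in binning.bins[v.name]:
            mask = labels == b.label
            lows[mask], highs[mask] = b.low, b.high
        frame[v.name] = lows + rng.random(len(labels)) * (highs - lows)
        if numeric_schema is not None:
            variables.append(numeric_schema.var(v.name))
        else:
            lo = binning.bins[v.name][0].low
            hi = binning.bins[v.name][-1].high
            variables.append(Variable(v.name, NUMERIC, bounds=(lo, hi)))
    schema = Schema(tuple(variables), dataset.schema.target_name, dataset.schema.protected_name)
    return TabularDataset(schema, frame, dataset.role, dataset.provenance)


# ---------------------------------------------------------------------------
# Distribution distance
# ---------------------------------------------------------------------------

def total_variation(a: Iterable[str], b: Iterable[str]) -> float:
    pa = pd.Series(list(a)).value_counts(normalize=True)
    pb = pd.Series(list(b)).value_counts(normalize=True)
    support = pa.index.union(pb.index)
    return float(0.5 * (pa.reindex(support, fill_value=0) - pb.reindex(support, fill_value=0)).abs().sum())


def distribution_distance(column_a: pd.Series, column_b: pd.Series, kind: str) -> float:
    """Bounded [0,1] distance between two empirical distributions.

    Total variation ``0.5 * sum |p - q|`` for categorical columns, two-sample
    Kolmogorov–Smirnov statistic for numeric ones.
    """
    if len(column_a) == 0 or len(column_b) == 0:
        raise ValueError("distribution_distance requires nonempty columns")
    if kind == CATEGORICAL:
        return total_variation(column_a.astype(str), column_b.astype(str))
    if kind == NUMERIC:
        return float(stats.ks_2samp(
            column_a.to_numpy(dtype=float), column_b.to_numpy(dtype=float)
        ).statistic)
    raise ValueError(f"unknown kind {kind!r}")
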