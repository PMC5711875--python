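"""Spatiotemporal point data: containers, CSV I/O and light preprocessing.

A dataset is a tidy collection of point measurements: each sample carries a
location ``(x, y)`` in meters, a real-valued time ``t`` in years (annual
campaigns are stored as the campaign year), a variable name and a value.
Designs may be *heterotopic* — different variables observed at partially
different point sets — so co-location is resolved with a small tolerance
(spatial distance < 0.5 m and |Δt| < 1e-6 years) rather than exact key
matching, which is fragile to floating-point noise.

Preprocessing mirrors common geostatistical practice for skewed
concentration data: a base-2 log transform toward normality, and a Pearson
correlation matrix over co-located observations used to rank candidate
co-variables for cokriging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import (
    ConfigurationError,
    DomainError,
    DuplicateRecordError,
    InsufficientOverlapError,
    ParseError,
)

# Co-location tolerances: annual campaigns make time effectively discrete.
SPATIAL_TOL = 0.5  # meters
TEMPORAL_TOL = 1e-6  # years

DEFAULT_COLUMNS = {
    "sample_id": "id",
    "x": "x",
    "y": "y",
    "t": "t",
    "variable": "variable",
    "value": "value",
}


@dataclass(frozen=True)
class STPoint:
    """A point in space-time: easting/northing in meters, time in years."""

    x: float
    y: float
    t: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "t"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise DomainError(f"coordinate {name!r} is not finite: {v}")


@dataclass(frozen=True)
class STSample:
    """One measurement of one variable at one space-time point."""

    point: STPoint
    variable: str
    value: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.variable:
            raise DomainError("variable name must be non-empty")
        if not math.isfinite(self.value):
            raise DomainError(
                f"value of sample {self.sample_id!r} is not finite: {self.value}"
            )


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pearson correlation matrix over co-located observation pairs."""

    variables: tuple[str, ...]
    r: np.ndarray

    def loc(self, u: str, v: str) -> float:
        i, j = self.variables.index(u), self.variables.index(v)
        return float(self.r[i, j])

    def covariables_ranked(self, primary: str) -> list[str]:
        """Other variables sorted by decreasing |r| with the primary."""
        others = [v for v in self.variables if v != primary]
        return sorted(others, key=lambda v: -abs(self.loc(primary, v)))


class STDataset:
    """Heterotopic multi-variable spatiotemporal point dataset.

    Holds at most one value per (point, variable); points are identified up
    to the co-location tolerance. ``transform_log`` records, per variable,
    whether stored values are base-2 logarithms of the measured quantity.
    """

    def __init__(
        self,
        samples: list[STSample],
        variables: tuple[str, ...] | None = None,
        transform_log: dict[str, bool] | None = None,
    ) -> None:
        self.samples = list(samples)
        seen = sorted({s.variable for s in self.samples})
        if variables is None:
            variables = tuple(seen)
        else:
            missing = set(seen) - set(variables)
            if missing:
                raise ConfigurationError(
                    f"samples reference variables not listed: {sorted(missing)}"
                )
        self.variables = tuple(variables)
        self.transform_log = dict.fromkeys(self.variables, False)
        if transform_log:
            self.transform_log.update(transform_log)
        self._point_labels: np.ndarray | None = None
        self._check_duplicates()

    # ---- point identity -------------------------------------------------

    def point_labels(self) -> np.ndarray:
        """Integer label per sample; equal labels mean co-located points."""
        if self._point_labels is None:
            self._point_labels = _cluster_points(
                np.array([[s.point.x, s.point.y] for s in self.samples], float).reshape(-1, 2),
                np.array([s.point.t for s in self.samples], float),
            )
        return self._point_labels

    def _check_duplicates(self) -> None:
        if not self.samples:
            return
        labels = self.point_labels()
        seen: dict[tuple[int, str], int] = {}
        for i, s in enumerate(self.samples):
            key = (int(labels[i]), s.variable)
            if key in seen:
                j = seen[key]
                raise DuplicateRecordError(
                    f"samples {self.samples[j].sample_id!r} (row {j}) and "
                    f"{s.sample_id!r} (row {i}) duplicate variable "
                    f"{s.variable!r} at the same space-time point"
                )
            seen[key] = i

    # ---- accessors ------------------------------------------------------

    def samples_of(self, variable: str) -> list[STSample]:
        if variable not in self.variables:
            raise ConfigurationError(f"unknown variable {variable!r}")
        return [s for s in self.samples if s.variable == variable]

    def arrays(self, variable: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Coordinate/value arrays (x, y, t, value) for one variable."""
        ss = self.samples_of(variable)
        if not ss:
            return tuple(np.empty(0) for _ in range(4))  # type: ignore[return-value]
        x = np.array([s.point.x for s in ss])
        y = np.array([s.point.y for s in ss])
        t = np.array([s.point.t for s in ss])
        v = np.array([s.value for s in ss])
        return x, y, t, v

    def __len__(self) -> int:
        return len(self.samples)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [s.sample_id for s in self.samples],
                "x": [s.point.x for s in self.samples],
                "y": [s.point.y for s in self.samples],
                "t": [s.point.t for s in self.samples],
                "variable": [s.variable for s in self.samples],
                "value": [s.value for s in self.samples],
            }
        )


def _cluster_points(xy: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Union-find clustering of samples into co-located space-time points."""
    n = len(t)
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    if n > 1:
        tree = cKDTree(xy)
        for i, j in tree.query_pairs(SPATIAL_TOL):
            if abs(t[i] - t[j]) < TEMPORAL_TOL:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    roots = np.array([find(i) for i in range(n)])
    _, labels = np.unique(roots, return_inverse=True)
    return labels


# ---- CSV I/O ------------------------------------------------------------


def read_points_csv(path, column_map: dict[str, str] | None = None) -> STDataset:
    """Read a tidy points CSV (default columns ``id,x,y,t,variable,value``).

    ``column_map`` maps logical names (``x``, ``y``, ``t``, ``variable``,
    ``value``, ``sample_id``) to the actual CSV headers.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(cols)
        if unknown:
            raise ConfigurationError(f"unknown logical columns: {sorted(unknown)}")
        cols.update(column_map)
    df = pd.read_csv(path, dtype=str)
    required = ["x", "y", "t", "variable", "value"]
    for logical in required:
        if cols[logical] not in df.columns:
            raise ConfigurationError(
                f"column {cols[logical]!r} (for {logical!r}) missing from {path}"
            )
    has_id = cols["sample_id"] in df.columns
    samples = []
    for idx, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        try:
            x, y, t = (float(rec[cols[c]]) for c in ("x", "y", "t"))
            value = float(rec[cols["value"]])
        except (TypeError, ValueError) as exc:
            raise ParseError(f"non-numeric coordinate or value at row {idx}: {exc}") from exc
        sid = str(rec[cols["sample_id"]]) if has_id else f"row{idx}"
        samples.append(
            STSample(STPoint(x, y, t), str(rec[cols["variable"]]), value, sid)
        )
    return STDataset(samples)


def write_points_csv(dataset: STDataset, path) -> None:
    """Write the tidy CSV dialect read by :func:`read_points_csv`.

    Floats are written with ``repr`` precision, so a write/read round trip
    is lossless.
    """
    dataset.to_dataframe().to_csv(path, index=False)


# ---- preprocessing ------------------------------------------------------


def log2_transform(dataset: STDataset, variables: list[str]) -> STDataset:
    """Replace values of the named variables by their base-2 logarithms."""
    for v in variables:
        if v not in dataset.variables:
            raise ConfigurationError(f"unknown variable {v!r}")
        if dataset.transform_log[v]:
            raise ConfigurationError(f"variable {v!r} is already log2-transformed")
    target = set(variables)
    out = []
    for s in dataset.samples:
        if s.variable in target:
            if s.value <= 0:
                raise DomainError(
                    f"sample {s.sample_id!r} of {s.variable!r} has non-positive "
                    f"value {s.value}; log2 transform undefined"
                )
            s = replace(s, value=math.log2(s.value))
        out.append(s)
    flags = dict(dataset.transform_log)
    flags.update(dict.fromkeys(target, True))
    return STDataset(out, dataset.variables, flags)


def inverse_log2_transform(dataset: STDataset, variables: list[str] | None = None) -> STDataset:
    """Undo :func:`log2_transform` (values become ``2**value``)."""
    if variables is None:
        variables = [v for v, f in dataset.transform_log.items() if f]
    for v in variables:
        if not dataset.transform_log.get(v, False):
            raise ConfigurationError(f"variable {v!r} is not log2-transformed")
    target = set(variables)
    out = [
        replace(s, value=2.0 ** s.value) if s.variable in target else s
        for s in dataset.samples
    ]
    flags = dict(dataset.transform_log)
    flags.update(dict.fromkeys(target, False))
    return STDataset(out, dataset.variables, flags)


def pearson_matrix(dataset: STDataset, min_pairs: int = 3) -> CorrelationMatrix:
    """Pearson correlation matrix computed over co-located observations.

    For each variable pair only samples sharing a space-time point (within
    the co-location tolerance) contribute; at least ``min_pairs`` common
    points are required per pair.
    """
    labels = dataset.point_labels()
    by_var: dict[str, dict[int, float]] = {v: {} for v in dataset.variables}
    for lab, s in zip(labels, dataset.samples):
        by_var[s.variable][int(lab)] = s.value
    p = len(dataset.variables)
    r = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            u, v = dataset.variables[i], dataset.variables[j]
            common = sorted(set(by_var[u]) & set(by_var[v]))
            if len(common) < min_pairs:
                raise InsufficientOverlapError(
                    f"only {len(common)} co-located points for pair "
                    f"({u!r}, {v!r}); need at least {min_pairs}"
                )
            a = np.array([by_var[u][k] for k in common])
            b = np.array([by_var[v][k] for k in common])
            r[i, j] = r[j, i] = np.corrcoef(a, b)[0, 1]
    return CorrelationMatrix(dataset.variables, r)
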