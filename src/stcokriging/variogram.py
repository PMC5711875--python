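"""Experimental spatiotemporal semivariograms and cross-semivariograms.

The empirical semivariogram of a variable z is half the average squared
increment over sample pairs falling in a space-time lag class:

    gamma(h_S, h_T) = 1/(2 N) * sum [z(s, t) - z(s + h_S, t + h_T)]^2

and the cross-semivariogram of two variables u, v replaces the square by
the product of the two variables' increments over *fully co-located* pairs
(both variables measured at both points). Lags are classed on a grid of
spatial distance bins crossed with discrete temporal lags (annual campaigns
make time effectively discrete); each class keeps its pair count and the
arithmetic mean of contributing spatial distances, which is where fitted
models are later evaluated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .data import STDataset
from .errors import DomainError, InsufficientDataError, InsufficientOverlapError


@dataclass(frozen=True)
class LagGrid:
    """Space-time lag classes: spatial distance bins x temporal target lags.

    A pair with spatial separation d and temporal separation dt contributes
    to spatial bin k iff ``spatial_edges[k] <= d < spatial_edges[k+1]`` and
    to temporal lag h_T iff ``|dt - h_T| <= temporal_tol``. Pairs beyond the
    last spatial edge are dropped.
    """

    spatial_edges: tuple[float, ...]
    temporal_lags: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0)
    temporal_tol: float = 0.25

    def __post_init__(self) -> None:
        e = np.asarray(self.spatial_edges, float)
        if len(e) < 2 or np.any(np.diff(e) <= 0):
            raise DomainError("spatial_edges must be strictly increasing, length >= 2")
        if e[0] != 0:
            raise DomainError("first spatial edge must be 0")
        if self.temporal_tol < 0:
            raise DomainError("temporal_tol must be >= 0")
        if any(h < 0 for h in self.temporal_lags):
            raise DomainError("temporal lags must be >= 0")

    @property
    def n_spatial(self) -> int:
        return len(self.spatial_edges) - 1


@dataclass(frozen=True)
class VariogramBin:
    """One lag class: mean spatial lag, temporal lag, estimate, pair count."""

    s_bin: int  # index of the spatial distance class
    h_S_center: float  # mean spatial lag of contributing pairs (m)
    h_T: float  # temporal lag (years)
    gamma_hat: float  # NaN when the class is empty
    n_pairs: int


@dataclass(frozen=True)
class EmpiricalVariogram:
    """Binned gamma-hat surface for one variable pair (auto when u == v)."""

    var_u: str
    var_v: str
    bins: tuple[VariogramBin, ...]
    grid: LagGrid

    @property
    def is_auto(self) -> bool:
        return self.var_u == self.var_v

    def nonempty(self) -> list[VariogramBin]:
        return [b for b in self.bins if b.n_pairs > 0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "var_u": self.var_u,
                "var_v": self.var_v,
                "h_S_center": [b.h_S_center for b in self.bins],
                "h_T": [b.h_T for b in self.bins],
                "gamma_hat": [b.gamma_hat for b in self.bins],
                "n_pairs": [b.n_pairs for b in self.bins],
                "s_bin": [b.s_bin for b in self.bins],
            }
        )


def default_lag_grid(
    dataset: STDataset,
    n_spatial: int = 12,
    temporal_lags: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0),
    temporal_tol: float = 0.25,
) -> LagGrid:
    """Equal-width spatial bins from 0 to half the maximum pairwise distance."""
    xy = np.array([[s.point.x, s.point.y] for s in dataset.samples], float).reshape(-1, 2)
    xy = np.unique(xy, axis=0)
    if len(xy) < 2:
        raise InsufficientDataError("need at least two distinct locations")
    dmax = _max_pairwise_distance(xy)
    edges = tuple(np.linspace(0.0, dmax / 2.0, n_spatial + 1))
    return LagGrid(edges, tuple(temporal_lags), temporal_tol)


def _max_pairwise_distance(xy: np.ndarray) -> float:
    pts = xy
    if len(xy) > 50:
        try:
            pts = xy[ConvexHull(xy).vertices]
        except QhullError:  # degenerate (collinear) configurations
            pass
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    return float(d.max())


def _pair_lags(x, y, t):
    """Unordered pair separations: returns (i, j, d_spatial, d_temporal)."""
    i, j = np.triu_indices(len(x), k=1)
    ds = np.hypot(x[i] - x[j], y[i] - y[j])
    dt = np.abs(t[i] - t[j])
    return i, j, ds, dt


def _bin_products(ds, dt, prod, grid: LagGrid) -> list[VariogramBin]:
    """Accumulate half-mean increment products on the lag grid."""
    edges = np.asarray(grid.spatial_edges)
    nb = grid.n_spatial
    sidx = np.searchsorted(edges, ds, side="right") - 1
    in_space = (sidx >= 0) & (sidx < nb)
    bins = []
    for h_T in grid.temporal_lags:
        in_time = np.abs(dt - h_T) <= grid.temporal_tol
        for k in range(nb):
            m = in_space & in_time & (sidx == k)
            n = int(m.sum())
            if n:
                center = float(ds[m].mean())
                gamma = float(prod[m].sum() / (2.0 * n))
            else:
                center = float(0.5 * (edges[k] + edges[k + 1]))
                gamma = float("nan")
            bins.append(VariogramBin(k, center, float(h_T), gamma, n))
    return bins


def empirical_semivariogram(
    dataset: STDataset, variable: str, grid: LagGrid
) -> EmpiricalVariogram:
    """Experimental auto-semivariogram of one variable on the lag grid."""
    x, y, t, z = dataset.arrays(variable)
    if len(z) < 2:
        raise InsufficientDataError(
            f"need at least 2 samples of {variable!r}, have {len(z)}"
        )
    _, _, ds, dt = _pair_lags(x, y, t)
    i, j = np.triu_indices(len(x), k=1)
    prod = (z[i] - z[j]) ** 2
    return EmpiricalVariogram(variable, variable, tuple(_bin_products(ds, dt, prod, grid)), grid)


def empirical_cross_semivariogram(
    dataset: STDataset, var_u: str, var_v: str, grid: LagGrid
) -> EmpiricalVariogram:
    """Experimental cross-semivariogram over fully co-located point pairs.

    Only space-time points where *both* variables are measured contribute;
    swapping ``var_u`` and ``var_v`` yields identical bins.
    """
    if var_u == var_v:
        return empirical_semivariogram(dataset, var_u, grid)
    labels = dataset.point_labels()
    vals: dict[str, dict[int, float]] = {var_u: {}, var_v: {}}
    coords: dict[int, tuple[float, float, float]] = {}
    for lab, s in zip(labels, dataset.samples):
        if s.variable in vals:
            vals[s.variable][int(lab)] = s.value
            coords[int(lab)] = (s.point.x, s.point.y, s.point.t)
    common = sorted(set(vals[var_u]) & set(vals[var_v]))
    if len(common) < 2:
        raise InsufficientOverlapError(
            f"only {len(common)} points carry both {var_u!r} and {var_v!r}"
        )
    x = np.array([coords[k][0] for k in common])
    y = np.array([coords[k][1] for k in common])
    t = np.array([coords[k][2] for k in common])
    zu = np.array([vals[var_u][k] for k in common])
    zv = np.array([vals[var_v][k] for k in common])
    i, j, ds, dt = _pair_lags(x, y, t)
    prod = (zu[i] - zu[j]) * (zv[i] - zv[j])
    return EmpiricalVariogram(var_u, var_v, tuple(_bin_products(ds, dt, prod, grid)), grid)


def marginal_profiles(
    ev: EmpiricalVariogram,
) -> tuple[list[tuple[float, float, int]], list[tuple[float, float, int]]]:
    """1-D diagnostic margins of the gamma-hat surface.

    Returns ``(spatial, temporal)``: the spatial profile collects nonempty
    bins at h_T = 0, the temporal profile the nonempty bins of the smallest
    populated spatial distance class.
    """
    nonempty = ev.nonempty()
    spatial = sorted(
        (b.h_S_center, b.gamma_hat, b.n_pairs) for b in nonempty if b.h_T == 0.0
    )
    if not spatial:
        warnings.warn(f"{ev.var_u} x {ev.var_v}: spatial margin (h_T=0) is empty")
    if nonempty:
        first = min(b.s_bin for b in nonempty)
        temporal = sorted(
            (b.h_T, b.gamma_hat, b.n_pairs) for b in nonempty if b.s_bin == first
        )
    else:
        temporal = []
    if not temporal:
        warnings.warn(f"{ev.var_u} x {ev.var_v}: temporal margin is empty")
    return spatial, temporal


# ---- CSV export/import --------------------------------------------------


def write_variograms_csv(evs: list[EmpiricalVariogram], path) -> None:
    pd.concat([ev.to_dataframe() for ev in evs], ignore_index=True).to_csv(
        path, index=False
    )


def read_variograms_csv(path, grid: LagGrid | None = None) -> list[EmpiricalVariogram]:
    """Rebuild empirical variograms from the CSV written by this module.

    The lag grid is reconstructed loosely (edges are only needed for
    re-binning, not for fitting); when absent a surrogate grid spanning the
    observed centers is attached.
    """
    df = pd.read_csv(path)
    out = []
    for (u, v), g in df.groupby(["var_u", "var_v"], sort=True):
        bins = tuple(
            VariogramBin(
                int(r.s_bin), float(r.h_S_center), float(r.h_T), float(r.gamma_hat), int(r.n_pairs)
            )
            for r in g.itertuples(index=False)
        )
        if grid is None:
            hi = max(b.h_S_center for b in bins) * 2 + 1.0
            n_s = max(b.s_bin for b in bins) + 1
            gr = LagGrid(
                tuple(np.linspace(0, hi, n_s + 1)),
                tuple(sorted({b.h_T for b in bins})),
                0.25,
            )
        else:
            gr = grid
        out.append(EmpiricalVariogram(str(u), str(v), bins, gr))
    return out
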