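"""Spatiotemporal cokriging: system assembly, solving, grids and LOOCV.

Prediction of a primary variable at an unsampled space-time point x0 uses
the k nearest samples *per variable* under the shared space-time metric
h_ST = sqrt(h_S^2 + alpha h_T^2). The ordinary-cokriging system in
semivariogram form is

    [ Gamma  1_blocks ] [ lambda ]   [ b   ]
    [ 1_blocks^T  0   ] [ psi    ] = [ e_u ]

where Gamma holds (cross-)semivariances between neighbor samples, b the
(cross-)semivariances to the target, and the unbiasedness rows force the
primary weights to sum to 1 and each secondary variable's weights to sum
to 0. The estimate is the weighted sum of all neighbor values and the
kriging variance is the dot product of the full solution vector (weights
and Lagrange multipliers) with the full right-hand side. With pair models
fitted independently the implied coregionalization may be invalid, in
which case the variance can come out negative; it is then floored at zero
with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import STDataset, STPoint, STSample
from .errors import (
    ConfigurationError,
    InsufficientDataError,
    STCKError,
    SingularSystemError,
)
from .models import ModelSet, SharedAnisotropy, st_lag

logger = logging.getLogger(__name__)

CONDITION_LIMIT = 1e12
CONSTRAINT_TOL = 1e-8


@dataclass
class Neighborhood:
    """Per-variable nearest samples around a target, under the ST metric."""

    target: STPoint
    variables: tuple[str, ...]  # primary first
    samples: dict[str, list[STSample]]
    distances: dict[str, np.ndarray]
    k: int


@dataclass
class KrigingSystem:
    """Assembled cokriging matrices for one target point."""

    lhs: np.ndarray
    rhs: np.ndarray
    variables: tuple[str, ...]
    counts: tuple[int, ...]  # neighbors per variable, same order

    @property
    def n_samples(self) -> int:
        return int(sum(self.counts))


@dataclass
class KrigingSolution:
    """Weights, Lagrange multipliers, estimate and kriging variance."""

    weights: dict[str, np.ndarray]
    multipliers: dict[str, float]
    estimate: float
    variance: float


def find_neighbors(
    dataset: STDataset,
    target: STPoint,
    variables: list[str] | tuple[str, ...],
    k: int,
    anisotropy: SharedAnisotropy,
    exclude: set[STSample] | frozenset[STSample] | None = None,
) -> Neighborhood:
    """k nearest samples of each variable under the shared ST metric.

    Ranking is by ``(st_distance, sample_id)`` — a stable, deterministic
    tie-break. ``exclude`` removes specific samples (used by LOOCV). The
    first variable is the primary and must retain at least one sample.
    """
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    exclude = exclude or set()
    samples: dict[str, list[STSample]] = {}
    distances: dict[str, np.ndarray] = {}
    kept_vars: list[str] = []
    for vi, var in enumerate(variables):
        cands = [s for s in dataset.samples_of(var) if s not in exclude]
        if not cands:
            if vi == 0:
                raise InsufficientDataError(
                    f"no samples of primary variable {var!r} available"
                )
            continue  # a secondary with no data contributes nothing
        d = np.array(
            [
                st_lag(
                    np.hypot(s.point.x - target.x, s.point.y - target.y),
                    abs(s.point.t - target.t),
                    anisotropy.alpha,
                )
                for s in cands
            ]
        )
        order = sorted(range(len(cands)), key=lambda i: (d[i], cands[i].sample_id))
        take = order[: min(k, len(cands))]
        samples[var] = [cands[i] for i in take]
        distances[var] = d[take]
        kept_vars.append(var)
    return Neighborhood(target, tuple(kept_vars), samples, distances, k)


def assemble_system(nb: Neighborhood, ms: ModelSet, primary: str) -> KrigingSystem:
    """Build the ordinary-cokriging matrices for one neighborhood."""
    if primary != nb.variables[0]:
        raise ConfigurationError(
            f"primary {primary!r} must be the neighborhood's first variable"
        )
    vars_ = nb.variables
    counts = tuple(len(nb.samples[v]) for v in vars_)
    n = sum(counts)
    p = len(vars_)
    dim = n + p
    lhs = np.zeros((dim, dim))
    rhs = np.zeros(dim)
    offsets = np.concatenate([[0], np.cumsum(counts)])

    coords = {
        v: np.array(
            [[s.point.x, s.point.y, s.point.t] for s in nb.samples[v]], float
        ).reshape(-1, 3)
        for v in vars_
    }
    for a, va in enumerate(vars_):
        ca = coords[va]
        for b, vb in enumerate(vars_):
            if b < a:
                continue
            cb = coords[vb]
            h_S = np.hypot(
                ca[:, None, 0] - cb[None, :, 0], ca[:, None, 1] - cb[None, :, 1]
            )
            h_T = np.abs(ca[:, None, 2] - cb[None, :, 2])
            block = np.atleast_2d(ms.gamma(va, vb, h_S, h_T))
            sl_a = slice(offsets[a], offsets[a + 1])
            sl_b = slice(offsets[b], offsets[b + 1])
            lhs[sl_a, sl_b] = block
            if b != a:
                lhs[sl_b, sl_a] = block.T
        # unbiasedness columns/rows and the right-hand side b-block
        lhs[offsets[a] : offsets[a + 1], n + a] = 1.0
        lhs[n + a, offsets[a] : offsets[a + 1]] = 1.0
        h_S0 = np.hypot(ca[:, 0] - nb.target.x, ca[:, 1] - nb.target.y)
        h_T0 = np.abs(ca[:, 2] - nb.target.t)
        rhs[offsets[a] : offsets[a + 1]] = np.atleast_1d(
            ms.gamma(primary, va, h_S0, h_T0)
        )
        rhs[n + a] = 1.0 if va == primary else 0.0
    return KrigingSystem(lhs, rhs, vars_, counts)


def solve_and_predict(
    sys: KrigingSystem, nb: Neighborhood, primary: str
) -> KrigingSolution:
    """Solve the cokriging system; return weights, estimate and variance."""
    cond = np.linalg.cond(sys.lhs)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise SingularSystemError(
            f"kriging matrix is singular or ill-conditioned (cond={cond:.3g}); "
            "duplicate or near-duplicate sample points are the usual cause"
        )
    sol = np.linalg.solve(sys.lhs, sys.rhs)
    n = sys.n_samples
    offsets = np.concatenate([[0], np.cumsum(sys.counts)])
    weights = {
        v: sol[offsets[i] : offsets[i + 1]] for i, v in enumerate(sys.variables)
    }
    multipliers = {v: float(sol[n + i]) for i, v in enumerate(sys.variables)}
    estimate = 0.0
    for v in sys.variables:
        z = np.array([s.value for s in nb.samples[v]])
        estimate += float(weights[v] @ z)
    variance = float(sol @ sys.rhs)
    if variance < 0.0:
        if variance < -CONSTRAINT_TOL:
            warnings.warn(
                f"negative kriging variance {variance:.3g} floored at 0; the "
                "model set is not a valid coregionalization"
            )
        variance = 0.0
    return KrigingSolution(weights, multipliers, estimate, variance)


def predict_point(
    dataset: STDataset,
    ms: ModelSet,
    primary: str,
    covariables: list[str],
    target: STPoint,
    k: int = 20,
    exclude: set[STSample] | None = None,
) -> KrigingSolution:
    """Cokriging prediction of the primary variable at one target point."""
    nb = find_neighbors(
        dataset, target, [primary, *covariables], k, ms.anisotropy, exclude
    )
    sys = assemble_system(nb, ms, primary)
    return solve_and_predict(sys, nb, primary)


@dataclass(frozen=True)
class GridSpec:
    """Regular prediction grid: spatial extent, cell size, one time slice."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float
    cell: float
    t: float

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        xs = np.arange(self.xmin + self.cell / 2, self.xmax, self.cell)
        ys = np.arange(self.ymin + self.cell / 2, self.ymax, self.cell)
        if len(xs) == 0 or len(ys) == 0:
            raise ConfigurationError("grid specification yields no cells")
        return xs, ys


LOG2_BIAS = np.log(2.0) / 2.0


def back_transform_log2(estimate, variance, bias_correction: bool = False):
    """Return predictions on the original scale from log2-scale kriging.

    Default is the naive ``2**z``; with ``bias_correction`` the lognormal
    correction ``2**(z + sigma^2 * ln2 / 2)`` is applied instead.
    """
    z = np.asarray(estimate, float)
    if bias_correction:
        z = z + np.asarray(variance, float) * LOG2_BIAS
    return 2.0**z


def predict_grid(
    dataset: STDataset,
    ms: ModelSet,
    primary: str,
    covariables: list[str],
    grid: GridSpec,
    k: int = 20,
    back_transform: bool = False,
    bias_correction: bool = False,
) -> pd.DataFrame:
    """Predict on a regular grid; failed cells are NaN, never fatal.

    When ``back_transform`` is set and the primary is log2-transformed,
    estimates are returned on the original measurement scale.
    """
    xs, ys = grid.centers()
    rows = []
    do_bt = back_transform and dataset.transform_log.get(primary, False)
    for y in ys:
        for x in xs:
            target = STPoint(float(x), float(y), grid.t)
            try:
                sol = predict_point(dataset, ms, primary, covariables, target, k)
                est, var = sol.estimate, sol.variance
                if do_bt:
                    est = float(back_transform_log2(est, var, bias_correction))
            except STCKError as exc:
                logger.warning("grid cell (%g, %g) failed: %s", x, y, exc)
                est, var = float("nan"), float("nan")
            rows.append((float(x), float(y), grid.t, est, var))
    return pd.DataFrame(rows, columns=["x", "y", "t", "estimate", "variance"])


@dataclass
class ValidationReport:
    """Leave-one-out cross-validation outcome for one configuration."""

    primary: str
    covariables: tuple[str, ...]
    k: int
    pairs: list[tuple[float, float]]  # (observed, predicted)
    variances: list[float]
    n_failed: int = 0

    @property
    def rmse(self) -> float:
        obs, pred = np.array(self.pairs).T
        return float(np.sqrt(np.mean((obs - pred) ** 2)))

    @property
    def mean_variance(self) -> float:
        return float(np.mean(self.variances))

    def to_dataframe(self) -> pd.DataFrame:
        obs, pred = np.array(self.pairs).T
        return pd.DataFrame(
            {"observed": obs, "predicted": pred, "variance": self.variances}
        )


def loocv(
    dataset: STDataset,
    ms: ModelSet,
    primary: str,
    covariables: list[str],
    k: int = 20,
    delete_all_at_point: bool = False,
) -> ValidationReport:
    """Leave-one-out validation of the primary variable.

    Each primary sample is removed in turn and predicted from the rest. By
    default only the primary value is deleted; co-variable values measured
    at the same point stay available (collocated-cokriging behavior).
    ``delete_all_at_point`` removes every variable's sample at that point
    instead. Points whose prediction fails are skipped and counted.
    """
    primaries = dataset.samples_of(primary)
    if len(primaries) < 2:
        raise InsufficientDataError("LOOCV needs at least 2 primary samples")
    labels = dataset.point_labels()
    label_of = {s: int(lab) for s, lab in zip(dataset.samples, labels)}
    pairs: list[tuple[float, float]] = []
    variances: list[float] = []
    n_failed = 0
    for held in primaries:
        if delete_all_at_point:
            excl = {s for s in dataset.samples if label_of[s] == label_of[held]}
        else:
            excl = {held}
        try:
            sol = predict_point(
                dataset, ms, primary, covariables, held.point, k, exclude=excl
            )
        except STCKError as exc:
            logger.warning("LOOCV failed at sample %r: %s", held.sample_id, exc)
            n_failed += 1
            continue
        pairs.append((held.value, sol.estimate))
        variances.append(sol.variance)
    if not pairs:
        raise InsufficientDataError("every LOOCV prediction failed")
    return ValidationReport(primary, tuple(covariables), k, pairs, variances, n_failed)
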