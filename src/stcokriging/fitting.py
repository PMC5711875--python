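"""Joint GA fitting of all auto- and cross-variogram models.

All pair models are fitted *simultaneously* because they share one
anisotropy ratio alpha: the chromosome concatenates five parameters
(C0, CS, aS, CST, aST) per variable pair plus the single alpha. The
temporal slopes CT are pre-estimated from the temporal margin of each
empirical variogram (ordinary least squares on the first spatial distance
class) and held fixed, so for p = 4 variables the search space has
5 * 10 + 1 = 51 free parameters.

The objective is a weighted sum of squared deviations between empirical
and modeled semivariances over all populated lag classes,

    sum_i w_i * (gamma_hat_i - gamma(h_Si, h_Ti))^2,

with w_i = N_i / sqrt(gamma_hat_i): classes with many pairs count more,
classes with large semivariance (noisier on the variance scale) count
less. For cross-variogram classes with gamma_hat <= 0 the weight uses
|gamma_hat| floored at 1e-6, preserving the down-weighting intent where
the literal formula is undefined.

The optimizer is a real-coded genetic algorithm: tournament selection,
blend (BLX-alpha) crossover, per-gene Gaussian mutation, one elite. It is
deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DomainError, InsufficientDataError
from .models import (
    BilonickModel,
    ModelSet,
    SharedAnisotropy,
    _pair_key,
    eval_component,
    st_lag,
)
from .variogram import EmpiricalVariogram

WEIGHT_FLOOR = 1e-6


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings (all configurable; defaults are generous)."""

    population_size: int = 100
    generations: int = 500
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    mutation_sigma_frac: float = 0.05  # initial sigma as fraction of bound width
    mutation_sigma_final_frac: float = 1e-4  # sigma anneals geometrically to this
    blx_alpha: float = 0.5
    tournament_size: int = 3
    elitism: int = 1
    survivor_selection: str = "plus"  # "plus" (parents compete) or "generational"
    restarts: int = 3  # independent runs (derived seeds); best result kept
    seed: int = 20171201

    def __post_init__(self) -> None:
        if self.population_size < 10:
            raise ConfigurationError("population_size must be >= 10")
        for name in ("crossover_rate", "mutation_rate"):
            r = getattr(self, name)
            if not (0.0 <= r <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {r}")
        if self.generations < 1 or self.tournament_size < 1 or self.elitism < 0:
            raise ConfigurationError("generations/tournament_size/elitism invalid")
        if self.survivor_selection not in ("plus", "generational"):
            raise ConfigurationError(
                "survivor_selection must be 'plus' or 'generational'"
            )


@dataclass
class _PairData:
    """Flattened nonempty bins of one empirical variogram, with weights."""

    key: tuple[str, str]
    is_auto: bool
    h_S: np.ndarray
    h_T: np.ndarray
    gamma: np.ndarray
    weight: np.ndarray


@dataclass
class FitObjective:
    """Weighted least-squares objective data for a set of variable pairs."""

    pairs: list[_PairData]

    @classmethod
    def from_empiricals(cls, empiricals: list[EmpiricalVariogram]) -> "FitObjective":
        pairs = []
        for ev in empiricals:
            bins = [b for b in ev.nonempty() if np.isfinite(b.gamma_hat)]
            if not bins:
                raise InsufficientDataError(
                    f"pair {ev.var_u!r} x {ev.var_v!r} has no populated lag classes"
                )
            g = np.array([b.gamma_hat for b in bins])
            n = np.array([b.n_pairs for b in bins], float)
            w = n / np.sqrt(np.maximum(np.abs(g), WEIGHT_FLOOR))
            pairs.append(
                _PairData(
                    _pair_key(ev.var_u, ev.var_v),
                    ev.var_u == ev.var_v,
                    np.array([b.h_S_center for b in bins]),
                    np.array([b.h_T for b in bins]),
                    g,
                    w,
                )
            )
        return cls(pairs)

    @property
    def keys(self) -> list[tuple[str, str]]:
        return [p.key for p in self.pairs]


def estimate_ct(ev: EmpiricalVariogram) -> float:
    """Temporal slope CT: OLS slope of gamma-hat against h_T in the first
    populated spatial distance class. May be negative for cross-variograms."""
    nonempty = [b for b in ev.nonempty() if np.isfinite(b.gamma_hat)]
    if not nonempty:
        raise InsufficientDataError("empirical variogram has no populated classes")
    first = min(b.s_bin for b in nonempty)
    col = [b for b in nonempty if b.s_bin == first]
    h = np.array([b.h_T for b in col])
    g = np.array([b.gamma_hat for b in col])
    if len(np.unique(h)) < 2:
        raise InsufficientDataError(
            "need >= 2 temporal lags in the first spatial class to estimate CT"
        )
    return float(np.polyfit(h, g, 1)[0])


def fitness(ms: ModelSet, obj: FitObjective) -> float:
    """Weighted squared-error score of a ModelSet against empirical bins."""
    total = 0.0
    for p in obj.pairs:
        m = ms.get(*p.key)  # raises ConfigurationError if missing
        gm = np.atleast_1d(
            np.asarray(
                _eval_sum(
                    p.h_S, p.h_T, ms.anisotropy.alpha,
                    m.C0, m.CT, m.CS, m.aS, m.CST, m.aST, m.s_kind, m.st_kind,
                )
            )
        )
        total += float(np.sum(p.weight * (p.gamma - gm) ** 2))
    return total


def _eval_sum(h_S, h_T, alpha, C0, CT, CS, aS, CST, aST, s_kind, st_kind):
    hst = st_lag(h_S, h_T, alpha)
    val = (
        C0
        + CT * np.asarray(h_T, float)
        + eval_component(s_kind, CS, aS, h_S)
        + eval_component(st_kind, CST, aST, hst)
    )
    return np.where((np.asarray(h_S) == 0) & (np.asarray(h_T) == 0), 0.0, val)


@dataclass
class FitBounds:
    """Per-gene search intervals: dict key -> (lo, hi) arrays of length 5
    in the order (C0, CS, aS, CST, aST), plus the alpha interval. ``ct``
    optionally overrides the CT gene interval when CT is GA-searched."""

    per_pair: dict[tuple[str, str], np.ndarray]  # shape (5, 2)
    alpha: tuple[float, float]
    ct: tuple[float, float] | None = None


def default_bounds(obj: FitObjective) -> FitBounds:
    """Bounds spanning the data: sills up to 3x the largest |gamma-hat|
    (symmetric for cross pairs), ranges from the smallest populated lag to
    3x the largest, alpha wide enough that sqrt(alpha)*h_T spans space."""
    per_pair = {}
    max_h = max(float(p.h_S.max()) for p in obj.pairs)
    min_h = min(float(p.h_S[p.h_S > 0].min()) if np.any(p.h_S > 0) else max_h for p in obj.pairs)
    min_h = max(min_h, 1e-6)
    nonzero_ht = [float(p.h_T[p.h_T > 0].min()) for p in obj.pairs if np.any(p.h_T > 0)]
    min_ht = min(nonzero_ht) if nonzero_ht else 1.0
    for p in obj.pairs:
        gmax = 3.0 * float(np.abs(p.gamma).max())
        gmax = max(gmax, WEIGHT_FLOOR)
        lo_sill = 0.0 if p.is_auto else -gmax
        b = np.array(
            [
                [lo_sill, gmax],  # C0
                [lo_sill, gmax],  # CS
                [min_h, 3.0 * max_h],  # aS
                [lo_sill, gmax],  # CST
                [min_h, 3.0 * max_h],  # aST
            ]
        )
        per_pair[p.key] = b
    return FitBounds(per_pair, (0.0, (max_h / min_ht) ** 2))


@dataclass
class FitResult:
    """Outcome of a joint GA fit."""

    model_set: ModelSet
    fitness: float
    trace: np.ndarray  # best fitness per generation, nonincreasing
    ct_values: dict[tuple[str, str], float]


def fit(
    empiricals: list[EmpiricalVariogram],
    families: dict[tuple[str, str], tuple[str, str]] | None = None,
    config: GAConfig | None = None,
    bounds: FitBounds | None = None,
    fit_ct: bool = False,
) -> FitResult:
    """Jointly fit all pair models and the shared anisotropy ratio.

    Parameters
    ----------
    empiricals : one EmpiricalVariogram per variable pair (auto and cross).
    families : optional mapping pair-key -> (s_kind, st_kind); default
        spherical for both components.
    config : GA settings; defaults to :class:`GAConfig`.
    bounds : search intervals; derived from the data when omitted.
    fit_ct : include CT in the chromosome instead of pre-estimating it by
        OLS on the temporal margin (the default).
    """
    config = config or GAConfig()
    obj = FitObjective.from_empiricals(empiricals)
    for ev, p in zip(empiricals, obj.pairs):
        if len(p.gamma) < 5:
            raise InsufficientDataError(
                f"pair {p.key} has only {len(p.gamma)} populated classes; need >= 5"
            )
    bounds = bounds or default_bounds(obj)
    for key in obj.keys:
        if key not in bounds.per_pair:
            raise ConfigurationError(f"no bounds for pair {key}")
    fams = families or {}
    by_key = {p.key: p for p in obj.pairs}

    ct_values: dict[tuple[str, str], float] = {}
    if not fit_ct:
        for ev in empiricals:
            ct = estimate_ct(ev)
            if ev.var_u == ev.var_v:
                ct = max(ct, 0.0)  # auto temporal slopes must be nonnegative
            ct_values[_pair_key(ev.var_u, ev.var_v)] = ct

    # chromosome layout: per pair 5 genes (C0, CS, aS, CST, aST) or 6 with
    # CT appended, then alpha last
    keys = obj.keys
    genes_per_pair = 6 if fit_ct else 5
    ngenes = genes_per_pair * len(keys) + 1
    lo = np.empty(ngenes)
    hi = np.empty(ngenes)
    for i, key in enumerate(keys):
        b = bounds.per_pair[key]
        o = i * genes_per_pair
        lo[o : o + 5], hi[o : o + 5] = b[:, 0], b[:, 1]
        if fit_ct:
            if bounds.ct is not None:
                lo[o + 5], hi[o + 5] = bounds.ct
            else:
                # CT bounds follow the sill bounds scaled to a per-year slope
                span = max(by_key[key].h_T.max(), 1.0)
                lo[o + 5], hi[o + 5] = b[0, 0] / span, b[0, 1] / span
    # alpha is searched on the sqrt scale (a space-time velocity in m/yr):
    # the quadratic scale spans too many orders of magnitude for uniform
    # crossover/mutation steps to resolve realistic ratios
    lo[-1], hi[-1] = np.sqrt(bounds.alpha[0]), np.sqrt(bounds.alpha[1])
    if np.any(hi <= lo):
        raise ConfigurationError("infeasible bounds: need lower < upper per gene")

    s_kinds, st_kinds = [], []
    for key in keys:
        sk, stk = fams.get(key, ("spherical", "spherical"))
        s_kinds.append(sk)
        st_kinds.append(stk)

    def score(vec: np.ndarray) -> float:
        alpha = vec[-1] ** 2
        total = 0.0
        for i, key in enumerate(keys):
            o = i * genes_per_pair
            C0, CS, aS, CST, aST = vec[o : o + 5]
            CT = vec[o + 5] if fit_ct else ct_values[key]
            p = by_key[key]
            gm = _eval_sum(
                p.h_S, p.h_T, alpha, C0, CT, CS, aS, CST, aST, s_kinds[i], st_kinds[i]
            )
            total += float(np.sum(p.weight * (p.gamma - gm) ** 2))
        return total

    width = hi - lo
    # geometric annealing of the mutation scale: coarse exploration early,
    # fine refinement late
    decay = (config.mutation_sigma_final_frac / config.mutation_sigma_frac) ** (
        1.0 / max(config.generations - 1, 1)
    )

    def run_ga(run_seed: int) -> tuple[np.ndarray, float, np.ndarray]:
        rng = np.random.default_rng(run_seed)
        pop = rng.uniform(lo, hi, size=(config.population_size, ngenes))
        fit_vals = np.array([score(v) for v in pop])
        best_i = int(np.argmin(fit_vals))
        best_vec, best_f = pop[best_i].copy(), float(fit_vals[best_i])
        trace = np.empty(config.generations)
        for gen in range(config.generations):
            sigma = config.mutation_sigma_frac * decay**gen * width
            # tournament selection of parents
            idx = rng.integers(
                0, config.population_size,
                size=(config.population_size, config.tournament_size),
            )
            winners = idx[np.arange(config.population_size), np.argmin(fit_vals[idx], axis=1)]
            parents = pop[winners]
            # BLX-alpha blend crossover on consecutive couples
            children = parents.copy()
            for c in range(0, config.population_size - 1, 2):
                if rng.random() < config.crossover_rate:
                    p1, p2 = parents[c], parents[c + 1]
                    cmin = np.minimum(p1, p2)
                    cmax = np.maximum(p1, p2)
                    span = cmax - cmin
                    a, b = cmin - config.blx_alpha * span, cmax + config.blx_alpha * span
                    children[c] = rng.uniform(a, b)
                    children[c + 1] = rng.uniform(a, b)
            # per-gene Gaussian mutation
            mask = rng.random(children.shape) < config.mutation_rate
            children = children + mask * rng.normal(0.0, 1.0, children.shape) * sigma
            np.clip(children, lo, hi, out=children)
            # elitism: keep the best-so-far individual
            for e in range(min(config.elitism, config.population_size)):
                children[e] = best_vec
            child_vals = np.array([score(v) for v in children])
            if config.survivor_selection == "plus":
                # (mu + lambda) truncation: parents compete with children
                merged = np.vstack([children, pop])
                merged_vals = np.concatenate([child_vals, fit_vals])
                keep = np.argsort(merged_vals, kind="stable")[: config.population_size]
                pop, fit_vals = merged[keep], merged_vals[keep]
            else:
                pop, fit_vals = children, child_vals
            gi = int(np.argmin(fit_vals))
            if fit_vals[gi] < best_f:
                best_f = float(fit_vals[gi])
                best_vec = pop[gi].copy()
            trace[gen] = best_f
        return best_vec, best_f, trace

    best_vec, best_f, trace = run_ga(config.seed)
    for r in range(1, max(config.restarts, 1)):
        # fixed derived seeds keep multi-start runs reproducible
        vec, f, tr = run_ga((config.seed + r * 7919) % (2**31))
        if f < best_f:
            best_vec, best_f, trace = vec, f, tr

    models = []
    for i, key in enumerate(keys):
        o = i * genes_per_pair
        C0, CS, aS, CST, aST = best_vec[o : o + 5]
        CT = best_vec[o + 5] if fit_ct else ct_values[key]
        if key[0] == key[1]:  # auto-model sills are clipped to >= 0 by bounds
            C0, CS, CST = max(C0, 0.0), max(CS, 0.0), max(CST, 0.0)
            CT = max(CT, 0.0)
        models.append(
            BilonickModel(
                key[0], key[1], float(C0), float(CT), float(CS), float(aS),
                float(CST), float(aST), s_kinds[i], st_kinds[i],
            )
        )
        ct_values[key] = float(CT)
    ms = ModelSet.from_models(models, SharedAnisotropy(float(best_vec[-1] ** 2)))
    return FitResult(ms, best_f, trace, ct_values)
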