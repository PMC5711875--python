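"""Sum-metric (Bilonick-type) spatiotemporal variogram models.

Each auto- or cross-semivariogram is the sum of four parts — a nugget C0,
a linear temporal part CT*h_T, a bounded spatial component with sill CS and
range aS, and a bounded spatiotemporal component with sill CST and range
aST evaluated at the anisotropy-scaled metric

    h_ST = sqrt(h_S^2 + alpha * h_T^2)

where the geometric anisotropy ratio alpha (m^2/year^2) converts temporal
lag into spatial-equivalent units. A single alpha is shared by *all* models
of a fitted set: it defines one space-time distance, hence one notion of
"nearest neighbor", for every variable and variable pair.

By convention gamma(0, 0) = 0 exactly (the nugget applies to any strictly
positive lag); the kriging matrices use the same convention on their
diagonal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DomainError

FAMILIES = ("spherical", "gaussian", "exponential")

MODEL_SCHEMA = "stck-modelset/1"


@dataclass(frozen=True)
class SharedAnisotropy:
    """The single geometric space-time anisotropy ratio alpha (m^2/yr^2)."""

    alpha: float

    def __post_init__(self) -> None:
        if not (self.alpha >= 0):
            raise DomainError(f"alpha must be >= 0, got {self.alpha}")


def st_lag(h_S, h_T, alpha: float):
    """Combined space-time lag ``sqrt(h_S**2 + alpha * h_T**2)`` in meters.

    Accepts scalars or arrays; all inputs must be nonnegative.
    """
    h_S = np.asarray(h_S, float)
    h_T = np.asarray(h_T, float)
    if np.any(h_S < 0) or np.any(h_T < 0) or alpha < 0:
        raise DomainError("st_lag requires nonnegative lags and alpha")
    out = np.sqrt(h_S**2 + alpha * h_T**2)
    return float(out) if out.ndim == 0 else out


def eval_component(kind: str, sill: float, range_: float, h):
    """Semivariance contribution of one bounded component at lag(s) h.

    spherical:   C * (1.5 h/a - 0.5 (h/a)^3) for h < a, C beyond the range
    gaussian:    C * (1 - exp(-(h/a)^2))
    exponential: C * (1 - exp(-h/a))
    """
    if range_ <= 0:
        raise DomainError(f"range must be > 0, got {range_}")
    h = np.asarray(h, float)
    if np.any(h < 0):
        raise DomainError("lag must be >= 0")
    r = h / range_
    if kind == "spherical":
        out = sill * np.where(r < 1.0, 1.5 * r - 0.5 * r**3, 1.0)
    elif kind == "gaussian":
        out = sill * (1.0 - np.exp(-(r**2)))
    elif kind == "exponential":
        out = sill * (1.0 - np.exp(-r))
    else:
        raise ConfigurationError(f"unknown component family {kind!r}")
    return float(out) if out.ndim == 0 else out


def _pair_key(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class BilonickModel:
    """Sum-metric model parameters for one (unordered) variable pair.

    For auto-models (var_u == var_v) all sills must be nonnegative; cross
    sills may take any sign. Ranges are strictly positive.
    """

    var_u: str
    var_v: str
    C0: float
    CT: float
    CS: float
    aS: float
    CST: float
    aST: float
    s_kind: str = "spherical"
    st_kind: str = "spherical"

    def __post_init__(self) -> None:
        if self.aS <= 0 or self.aST <= 0:
            raise DomainError("ranges aS and aST must be > 0")
        for k in (self.s_kind, self.st_kind):
            if k not in FAMILIES:
                raise ConfigurationError(f"unknown component family {k!r}")
        if self.var_u == self.var_v:
            for name in ("C0", "CT", "CS", "CST"):
                if getattr(self, name) < 0:
                    raise DomainError(
                        f"auto-model {self.var_u!r}: {name} must be >= 0"
                    )

    @property
    def is_auto(self) -> bool:
        return self.var_u == self.var_v

    @property
    def key(self) -> tuple[str, str]:
        return _pair_key(self.var_u, self.var_v)


def eval_model(model: BilonickModel, h_S, h_T, anisotropy: SharedAnisotropy):
    """Total (cross-)semivariance at lag (h_S, h_T); exactly 0 at (0, 0)."""
    h_S = np.asarray(h_S, float)
    h_T = np.asarray(h_T, float)
    h_S, h_T = np.broadcast_arrays(h_S, h_T)
    hst = st_lag(h_S, h_T, anisotropy.alpha)
    val = (
        model.C0
        + model.CT * h_T
        + eval_component(model.s_kind, model.CS, model.aS, h_S)
        + eval_component(model.st_kind, model.CST, model.aST, hst)
    )
    val = np.where((h_S == 0) & (h_T == 0), 0.0, val)
    return float(val) if val.ndim == 0 else val


@dataclass(frozen=True)
class ModelSet:
    """A complete set of pair models sharing one anisotropy ratio."""

    models: dict[tuple[str, str], BilonickModel]
    anisotropy: SharedAnisotropy

    @classmethod
    def from_models(cls, models: list[BilonickModel], anisotropy: SharedAnisotropy) -> "ModelSet":
        d: dict[tuple[str, str], BilonickModel] = {}
        for m in models:
            if m.key in d:
                raise ConfigurationError(f"duplicate model for pair {m.key}")
            d[m.key] = m
        return cls(d, anisotropy)

    @property
    def variables(self) -> tuple[str, ...]:
        vs: set[str] = set()
        for u, v in self.models:
            vs.update((u, v))
        return tuple(sorted(vs))

    def get(self, u: str, v: str) -> BilonickModel:
        key = _pair_key(u, v)
        if key not in self.models:
            raise ConfigurationError(f"no model for pair {key}")
        return self.models[key]

    def gamma(self, u: str, v: str, h_S, h_T):
        return eval_model(self.get(u, v), h_S, h_T, self.anisotropy)

    def check_complete(self, variables: list[str] | tuple[str, ...]) -> None:
        for i, u in enumerate(variables):
            for v in variables[i:]:
                self.get(u, v)

    # ---- structured sill matrices --------------------------------------

    def sill_matrix(self, component: str) -> np.ndarray:
        """Symmetric matrix of one structure's sills over all variables."""
        attr = {"nugget": "C0", "T": "CT", "S": "CS", "ST": "CST"}[component]
        vs = self.variables
        m = np.zeros((len(vs), len(vs)))
        for i, u in enumerate(vs):
            for j, v in enumerate(vs):
                m[i, j] = getattr(self.get(u, v), attr)
        return m


@dataclass(frozen=True)
class ValidityReport:
    """Coregionalization diagnostics for a ModelSet (warnings, not errors).

    Checks, per structure (nugget, T, S, ST): the pairwise Cauchy-Schwarz
    bound |C_uv| <= sqrt(C_uu * C_vv), positive semidefiniteness of the
    sill matrix, and whether ranges and component families agree across the
    set (the linear-model-of-coregionalization layout). Violations mean
    kriging variances may come out negative; prediction still proceeds.
    """

    cauchy_schwarz_violations: tuple[str, ...]
    psd_violations: tuple[str, ...]
    structure_mismatches: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not (
            self.cauchy_schwarz_violations
            or self.psd_violations
            or self.structure_mismatches
        )

    @property
    def violations(self) -> tuple[str, ...]:
        return (
            self.cauchy_schwarz_violations
            + self.psd_violations
            + self.structure_mismatches
        )


def validity_report(ms: ModelSet, psd_tol: float = 1e-10) -> ValidityReport:
    """Diagnose whether a ModelSet is a valid coregionalization. Never raises."""
    vs = ms.variables
    cs_viol, psd_viol, mism = [], [], []
    for comp in ("nugget", "T", "S", "ST"):
        mat = ms.sill_matrix(comp)
        for i, u in enumerate(vs):
            for j in range(i + 1, len(vs)):
                v = vs[j]
                bound = np.sqrt(max(mat[i, i] * mat[j, j], 0.0))
                if abs(mat[i, j]) > bound + 1e-12:
                    cs_viol.append(
                        f"{comp}: |C_{u}x{v}|={abs(mat[i, j]):g} exceeds "
                        f"sqrt(C_{u}*C_{v})={bound:g}"
                    )
        if len(vs) > 1 and np.linalg.eigvalsh(mat).min() < -psd_tol * max(1.0, abs(mat).max()):
            psd_viol.append(f"{comp}: sill matrix is not positive semidefinite")
    if len(ms.models) > 1:
        mods = list(ms.models.values())
        for attr in ("aS", "aST", "s_kind", "st_kind"):
            vals = {getattr(m, attr) for m in mods}
            if len(vals) > 1:
                mism.append(
                    f"{attr} differs across pairs ({len(vals)} distinct values); "
                    "proportional-covariance/LMC structure does not hold"
                )
    return ValidityReport(tuple(cs_viol), tuple(psd_viol), tuple(mism))


# ---- model-file (JSON) serialization ------------------------------------


def model_set_to_dict(ms: ModelSet) -> dict:
    return {
        "schema": MODEL_SCHEMA,
        "alpha": ms.anisotropy.alpha,
        "models": [
            {
                "var_u": m.var_u,
                "var_v": m.var_v,
                "C0": m.C0,
                "CT": m.CT,
                "CS": m.CS,
                "aS": m.aS,
                "CST": m.CST,
                "aST": m.aST,
                "s_kind": m.s_kind,
                "st_kind": m.st_kind,
            }
            for _, m in sorted(ms.models.items())
        ],
    }


def model_set_from_dict(d: dict) -> ModelSet:
    if d.get("schema") != MODEL_SCHEMA:
        raise ConfigurationError(
            f"unsupported model file schema {d.get('schema')!r}; expected {MODEL_SCHEMA!r}"
        )
    models = [
        BilonickModel(
            var_u=str(r["var_u"]),
            var_v=str(r["var_v"]),
            C0=float(r["C0"]),
            CT=float(r["CT"]),
            CS=float(r["CS"]),
            aS=float(r["aS"]),
            CST=float(r["CST"]),
            aST=float(r["aST"]),
            s_kind=str(r.get("s_kind", "spherical")),
            st_kind=str(r.get("st_kind", "spherical")),
        )
        for r in d["models"]
    ]
    return ModelSet.from_models(models, SharedAnisotropy(float(d["alpha"])))


def save_model_file(ms: ModelSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model_set_to_dict(ms), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_model_file(path) -> ModelSet:
    with open(path, encoding="utf-8") as fh:
        return model_set_from_dict(json.load(fh))
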