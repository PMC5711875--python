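"""Workflow wiring: transform -> variography -> fit -> predict/cv/sweep.

A single RunConfig drives the whole chain with seeded reproducibility: the
global seed derives per-stage seeds by fixed offsets, so stages can be
re-run independently yet reproducibly. Every run writes a manifest
recording inputs (content hashes), seeds and package version, making runs
auditable; re-running with the same config and seed produces byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import STDataset, log2_transform, read_points_csv, write_points_csv
from .errors import ConfigurationError, STCKError
from .fitting import GAConfig, fit
from .kriging import loocv
from .models import ModelSet, load_model_file, save_model_file, validity_report
from .simulate import SamplingDesign, StructureSpec, SyntheticFieldSpec, simulate
from .variogram import (
    LagGrid,
    default_lag_grid,
    empirical_cross_semivariogram,
    empirical_semivariogram,
    write_variograms_csv,
)

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets (kept below 2**31 after derivation)
_SEED_SIM = 101
_SEED_GA = 211


def derive_seed(global_seed: int, offset: int) -> int:
    return int((int(global_seed) + offset) % (2**31))


@dataclass
class RunConfig:
    """Configuration of one workflow run (parsed from YAML or built in code)."""

    outdir: Path
    seed: int = 0
    input_csv: Path | None = None
    simulate: dict | None = None  # SyntheticFieldSpec recipe (see _spec_from_dict)
    primary: str = ""
    covariables: tuple[str, ...] = ()
    log2_variables: tuple[str, ...] = ()
    n_spatial_bins: int = 12
    temporal_lags: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0)
    temporal_tol: float = 0.25
    families: dict[tuple[str, str], tuple[str, str]] = field(default_factory=dict)
    ga: GAConfig | None = None
    k: int = 20
    k_range: tuple[int, int] = (4, 20)
    covariable_subsets: tuple[tuple[str, ...], ...] | None = None
    model_file: Path | None = None  # skip fitting, use this model set

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path | None = None) -> "RunConfig":
        base = base or Path(".")
        kwargs: dict = {}
        kwargs["outdir"] = base / raw.get("outdir", "stck_out")
        for key in ("seed", "primary", "n_spatial_bins", "temporal_tol", "k"):
            if key in raw:
                kwargs[key] = raw[key]
        for key in ("covariables", "log2_variables", "temporal_lags"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        if "k_range" in raw:
            kwargs["k_range"] = tuple(raw["k_range"])
        if "covariable_subsets" in raw:
            kwargs["covariable_subsets"] = tuple(
                tuple(s) for s in raw["covariable_subsets"]
            )
        if "input_csv" in raw:
            kwargs["input_csv"] = base / raw["input_csv"]
        if "model_file" in raw:
            kwargs["model_file"] = base / raw["model_file"]
        if "simulate" in raw:
            kwargs["simulate"] = raw["simulate"]
        if "families" in raw:
            kwargs["families"] = {
                tuple(sorted(k.split("|"))): tuple(v) for k, v in raw["families"].items()
            }
        if "ga" in raw:
            kwargs["ga"] = GAConfig(**raw["ga"])
        return cls(**kwargs)


def _spec_from_dict(d: dict, seed: int) -> SyntheticFieldSpec:
    variables = tuple(d["variables"])
    kwargs: dict = {"variables": variables, "seed": seed}
    if "nugget" in d:
        kwargs["nugget"] = np.asarray(d["nugget"], float)
    for key, attr in (("spatial", "spatial"), ("st", "spatio_temporal")):
        if key in d:
            s = d[key]
            kwargs[attr] = StructureSpec(
                s.get("kind", "spherical"), float(s["range"]), np.asarray(s["sill"], float)
            )
    for key in ("alpha", "jitter"):
        if key in d:
            kwargs[key] = float(d[key])
    if "ct" in d:
        kwargs["ct"] = np.asarray(d["ct"], float)
    if "means" in d:
        kwargs["means"] = tuple(d["means"])
    if "missingness" in d:
        kwargs["missingness"] = tuple(d["missingness"])
    if "design" in d:
        g = d["design"]
        kwargs["design"] = SamplingDesign(
            tuple(g.get("years", SamplingDesign.years)),
            tuple(g.get("n_per_year", SamplingDesign.n_per_year)),
            tuple(g.get("extent", SamplingDesign.extent)),
            g.get("n_sites", SamplingDesign.n_sites),
        )
    return SyntheticFieldSpec(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _all_pairs(variables: tuple[str, ...]) -> list[tuple[str, str]]:
    vs = sorted(variables)
    return [(u, v) for i, u in enumerate(vs) for v in vs[i:]]


def run_workflow(config: RunConfig) -> dict[str, Path]:
    """Execute the configured stages in order; returns artifact paths.

    Stages: obtain data (read CSV or simulate), log2 transform, empirical
    variography for every variable pair, joint GA fit (or load a model
    file), LOOCV, and an optional (k, co-variable subset) sweep. A stage
    failure aborts with the stage named; partial outputs stay on disk next
    to a FAILED marker.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {
            "simulate": derive_seed(config.seed, _SEED_SIM),
            "ga": derive_seed(config.seed, _SEED_GA),
        },
        "inputs": {},
        "decisions": {
            "neighbor_semantics": "k nearest per variable",
            "variance": "full solution vector dotted with full rhs; negatives floored at 0",
            "weight_floor": "fitness weights use |gamma_hat| floored at 1e-6",
            "loocv_deletion": "primary value only",
        },
    }
    stage = "load"
    try:
        if config.input_csv is not None:
            dataset = read_points_csv(config.input_csv)
            manifest["inputs"][str(config.input_csv)] = _sha256(Path(config.input_csv))
        elif config.simulate is not None:
            stage = "simulate"
            spec = _spec_from_dict(config.simulate, derive_seed(config.seed, _SEED_SIM))
            sim = simulate(spec)
            dataset = sim.dataset
            p = out / "points.csv"
            write_points_csv(dataset, p)
            artifacts["points"] = p
            tp = out / "truth_model.json"
            save_model_file(sim.truth, tp)
            artifacts["truth_model"] = tp
        else:
            raise ConfigurationError("config must provide input_csv or simulate")

        stage = "validate"
        primary = config.primary or dataset.variables[0]
        referenced = {primary, *config.covariables, *config.log2_variables}
        for subset in config.covariable_subsets or ():
            referenced.update(subset)
        missing = referenced - set(dataset.variables)
        if missing:
            raise ConfigurationError(
                f"config references unknown variables: {sorted(missing)}"
            )

        if config.log2_variables:
            stage = "transform"
            dataset = log2_transform(dataset, list(config.log2_variables))

        stage = "variogram"
        grid = default_lag_grid(
            dataset, config.n_spatial_bins, config.temporal_lags, config.temporal_tol
        )
        empiricals = []
        for u, v in _all_pairs(dataset.variables):
            if u == v:
                empiricals.append(empirical_semivariogram(dataset, u, grid))
            else:
                empiricals.append(empirical_cross_semivariogram(dataset, u, v, grid))
        vp = out / "variograms.csv"
        write_variograms_csv(empiricals, vp)
        artifacts["variograms"] = vp

        if config.model_file is not None:
            ms = load_model_file(config.model_file)
            manifest["inputs"][str(config.model_file)] = _sha256(Path(config.model_file))
        else:
            stage = "fit"
            ga = config.ga or GAConfig()
            ga = GAConfig(**{**ga.__dict__, "seed": derive_seed(config.seed, _SEED_GA)})
            result = fit(empiricals, families=config.families or None, config=ga)
            ms = result.model_set
            mp = out / "model.json"
            save_model_file(ms, mp)
            artifacts["model"] = mp
            tr = out / "fit_trace.csv"
            pd.DataFrame(
                {"generation": np.arange(len(result.trace)), "best_fitness": result.trace}
            ).to_csv(tr, index=False)
            artifacts["fit_trace"] = tr
            manifest["fitness"] = result.fitness
        manifest["validity"] = list(validity_report(ms).violations)

        stage = "cv"
        report = loocv(dataset, ms, primary, list(config.covariables), config.k)
        cvp = out / "cv.csv"
        df = report.to_dataframe()
        summary = pd.DataFrame(
            {
                "observed": [np.nan],
                "predicted": [np.nan],
                "variance": [report.mean_variance],
                "rmse": [report.rmse],
            }
        )
        df["rmse"] = np.nan
        pd.concat([df, summary], ignore_index=True).to_csv(cvp, index=False)
        artifacts["cv"] = cvp
        manifest["rmse"] = report.rmse

        if config.covariable_subsets is not None:
            stage = "sweep"
            ks = list(range(config.k_range[0], config.k_range[1] + 1))
            sw = sweep_loocv(
                dataset, ms, primary, list(config.covariable_subsets), ks
            )
            sp = out / "sweep.csv"
            sw.to_csv(sp, index=False)
            artifacts["sweep"] = sp
    except STCKError:
        (out / "FAILED").write_text(f"stage: {stage}\n", encoding="utf-8")
        logger.error("workflow failed during stage %r", stage)
        raise
    mp = out / "manifest.json"
    manifest["artifacts"] = {k: str(v) for k, v in artifacts.items()}
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    artifacts["manifest"] = mp
    return artifacts


def sweep_loocv(
    dataset: STDataset,
    ms: ModelSet,
    primary: str,
    subsets: list[tuple[str, ...]],
    ks: list[int],
) -> pd.DataFrame:
    """LOOCV RMSE and mean kriging variance over (k, co-variable subset).

    One row per requested combination; failed cells carry NaN and the
    sweep continues. Averages are over the LOOCV points of the primary
    variable.
    """
    if not subsets or not ks:
        raise ConfigurationError("sweep needs nonempty k list and subset list")
    rows = []
    for k, subset in itertools.product(ks, subsets):
        label = "+".join(subset) if subset else "(none)"
        try:
            rep = loocv(dataset, ms, primary, list(subset), k)
            rows.append((k, label, rep.mean_variance, rep.rmse, rep.n_failed))
        except STCKError as exc:
            logger.warning("sweep cell k=%d subset=%s failed: %s", k, label, exc)
            rows.append((k, label, float("nan"), float("nan"), -1))
    return pd.DataFrame(
        rows, columns=["k", "covariables", "mean_variance", "rmse", "n_failed"]
    )
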