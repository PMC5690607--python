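"""Reproducible multi-stage pipeline: simulate -> extract -> fit ->
evaluate -> interpret -> map.

Stages communicate only through declared files inside the run directory;
re-running a later stage after deleting an intermediate fails loudly
with the stage name.  A manifest records the config hash, per-stage
seeds, package versions and SHA-256 of every output, and re-running an
identical config reproduces every CSV bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cif import ConditionalInferenceForest, ForestConfig
from .evaluate import cross_validate, roc_points
from .geography import (
    attribution_map,
    attribution_scores,
    build_risk_sets,
    mean_velocity_per_species,
    overlay_product,
    richness_map,
    RISK_SET_NAMES,
)
from .grids import RangeAtlas, read_raster, write_raster
from .interpret import partial_dependence, permutation_importance, reference_profile
from .synthetic import WorldConfig, simulate
from .traits import dichotomize_series, read_trait_table
from .zonal import DEFAULT_FEATURES, FeatureMatrix, assemble_features

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "extract", "fit", "evaluate", "interpret", "map")
RASTER_LAYERS = (
    "cum_productivity", "min_productivity", "cv_productivity",
    "human_density", "night_lights", "land_cover", "velocity",
)


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    world: WorldConfig = field(default_factory=WorldConfig)
    forest: ForestConfig = field(default_factory=ForestConfig)
    seeds: dict = field(default_factory=dict)   # one per stochastic stage
    cv_k: int = 10
    latent_statuses: tuple = ("LC", "NT", "DD")
    velocity_thresholds: tuple = (0.5, 1.0)
    importance_reps: int = 3
    attribution_features: tuple = (
        "log_range_size", "log_body_mass", "mean_cv_productivity", "mean_human_density",
    )
    pd_features: tuple | None = None  # None -> every modeled feature

    REQUIRED_SEEDS = ("simulate", "fit", "evaluate", "interpret")

    def validate(self) -> None:
        self.world.validate()
        self.forest.validate()
        for stage in self.REQUIRED_SEEDS:
            if stage not in self.seeds:
                raise ValueError(f"config is missing a seed for stage {stage!r}")
            if not isinstance(self.seeds[stage], int):
                raise ValueError(f"seed for stage {stage!r} must be an integer")
        if self.cv_k < 2:
            raise ValueError("cv_k must be >= 2")
        if self.forest.n_trees < 1:
            raise ValueError("forest.n_trees must be >= 1")

    @classmethod
    def from_seed(cls, seed: int, **overrides) -> "PipelineConfig":
        """A default config with per-stage seeds derived from one master seed."""
        ss = np.random.SeedSequence(seed)
        seeds = {
            stage: int(child.generate_state(1)[0] % (2 ** 31))
            for stage, child in zip(cls.REQUIRED_SEEDS, ss.spawn(len(cls.REQUIRED_SEEDS)))
        }
        cfg = cls(seeds=seeds, **overrides)
        cfg.validate()
        return cfg

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "world" in d:
            d["world"] = WorldConfig(**d["world"])
        if "forest" in d:
            d["forest"] = ForestConfig(**d["forest"])
        for key in ("latent_statuses", "velocity_thresholds", "attribution_features", "pd_features"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r} requires {path.name}, which is missing from the run "
            f"directory; run the producing stage first"
        )
    return path


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, lineterminator="\n")


def _load_features(outdir: Path, stage: str) -> FeatureMatrix:
    fpath = _require(outdir / "features.csv", stage)
    kpath = _require(outdir / "feature_kinds.json", stage)
    data = pd.read_csv(fpath, index_col="species_id")
    with open(kpath) as fh:
        meta = json.load(fh)
    return FeatureMatrix(data=data, kinds=meta["kinds"], levels=meta["levels"])


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: PipelineConfig, outdir: Path) -> list[Path]:
    data = simulate(config.world, seed=config.seeds["simulate"])
    outputs = []
    rdir = outdir / "rasters"
    rdir.mkdir(exist_ok=True)
    for name, grid in data.rasters.items():
        p = rdir / f"{name}.asc"
        write_raster(grid, p)
        outputs.append(p)
    tpath = outdir / "traits.csv"
    _write_csv(data.traits, tpath)
    apath = outdir / "atlas.csv"
    data.atlas.to_csv(apath)
    gpath = outdir / "groundtruth.json"
    with open(gpath, "w") as fh:
        json.dump({"info": data.info,
                   "table": data.groundtruth.reset_index()
                   .rename(columns={"index": "species_id"}).to_dict(orient="list")},
                  fh, indent=1)
    return outputs + [tpath, apath, gpath]


def stage_extract(config: PipelineConfig, outdir: Path) -> list[Path]:
    table = read_trait_table(_require(outdir / "traits.csv", "extract"))
    rasters = {
        name: read_raster(
            _require(outdir / "rasters" / f"{name}.asc", "extract"),
            kind="categorical" if name == "land_cover" else "continuous", name=name,
        )
        for name in RASTER_LAYERS
    }
    grid = rasters["cum_productivity"]
    atlas = RangeAtlas.from_csv(_require(outdir / "atlas.csv", "extract"), grid)
    features = assemble_features(table, rasters, atlas)
    fpath = outdir / "features.csv"
    _write_csv(features.data, fpath, index=True)
    kpath = outdir / "feature_kinds.json"
    with open(kpath, "w") as fh:
        json.dump({"kinds": features.kinds, "levels": features.levels,
                   "meta": features.meta}, fh, indent=1)
    spath = outdir / "statuses.csv"
    _write_csv(table[["species_id", "redlist_status"]], spath)
    return [fpath, kpath, spath]


def _model_columns(features: FeatureMatrix) -> list[str]:
    return [c for c in DEFAULT_FEATURES if c in features.feature_names]


def stage_fit(config: PipelineConfig, outdir: Path) -> list[Path]:
    features = _load_features(outdir, "fit")
    statuses = pd.read_csv(_require(outdir / "statuses.csv", "fit"),
                           index_col="species_id")["redlist_status"]
    cols = _model_columns(features)
    X, names, kinds = features.to_matrix(cols)
    y = dichotomize_series(statuses.reindex(features.data.index)).to_numpy(dtype=float)
    forest = ConditionalInferenceForest.fit(
        X, y, names, kinds, config=config.forest, seed=config.seeds["fit"],
    )
    fpath = outdir / "forest.json"
    forest.to_json(fpath)
    prob = pd.DataFrame({
        "species_id": features.data.index,
        "probability": forest.predict_proba(X),
    })
    ppath = outdir / "probabilities.csv"
    _write_csv(prob, ppath)
    return [fpath, ppath]


def stage_evaluate(config: PipelineConfig, outdir: Path) -> list[Path]:
    features = _load_features(outdir, "evaluate")
    statuses = pd.read_csv(_require(outdir / "statuses.csv", "evaluate"),
                           index_col="species_id")["redlist_status"]
    cols = _model_columns(features)
    X, names, kinds = features.to_matrix(cols)
    y = dichotomize_series(statuses.reindex(features.data.index)).to_numpy(dtype=float)
    labeled = ~np.isnan(y)
    cv = cross_validate(
        X[labeled], y[labeled], names, kinds, k=config.cv_k,
        config=config.forest, seed=config.seeds["evaluate"],
    )
    mpath = outdir / "metrics.csv"
    _write_csv(cv.summary_frame(), mpath)
    fpath = outdir / "metrics_per_fold.csv"
    _write_csv(cv.per_fold, fpath)
    rpath = outdir / "roc_curve.csv"
    _write_csv(roc_points(cv.scores, cv.labels), rpath)
    tpath = outdir / "threshold.json"
    with open(tpath, "w") as fh:
        json.dump({"max_kappa_threshold": cv.threshold, "source": "pooled holdout scores",
                   "notes": cv.notes}, fh, indent=1)
    return [mpath, fpath, rpath, tpath]


def stage_interpret(config: PipelineConfig, outdir: Path) -> list[Path]:
    features = _load_features(outdir, "interpret")
    statuses = pd.read_csv(_require(outdir / "statuses.csv", "interpret"),
                           index_col="species_id")["redlist_status"]
    forest = ConditionalInferenceForest.from_json(_require(outdir / "forest.json", "interpret"))
    cols = _model_columns(features)
    X, _, _ = features.to_matrix(cols)
    y = dichotomize_series(statuses.reindex(features.data.index)).to_numpy(dtype=float)
    imp = permutation_importance(
        forest, X, y, n_reps=config.importance_reps, seed=config.seeds["interpret"],
    )
    ipath = outdir / "importance.csv"
    _write_csv(imp.table, ipath)
    sub = FeatureMatrix(
        data=features.data[cols], kinds={k: features.kinds[k] for k in cols},
        levels={k: v for k, v in features.levels.items() if k in cols},
    )
    profile = reference_profile(sub)
    outputs = [ipath]
    pd_features = config.pd_features or cols
    for feat in pd_features:
        curve = partial_dependence(forest, sub, feat, profile=profile)
        p = outdir / f"pd_{feat}.csv"
        _write_csv(curve.to_frame(), p)
        outputs.append(p)
    return outputs


def stage_map(config: PipelineConfig, outdir: Path) -> list[Path]:
    features = _load_features(outdir, "map")
    statuses = pd.read_csv(_require(outdir / "statuses.csv", "map"),
                           index_col="species_id")["redlist_status"]
    forest = ConditionalInferenceForest.from_json(_require(outdir / "forest.json", "map"))
    prob = pd.read_csv(_require(outdir / "probabilities.csv", "map"),
                       index_col="species_id")["probability"]
    with open(_require(outdir / "threshold.json", "map")) as fh:
        threshold = json.load(fh)["max_kappa_threshold"]
    velocity = read_raster(_require(outdir / "rasters" / "velocity.asc", "map"),
                           kind="continuous", name="velocity")
    atlas = RangeAtlas.from_csv(_require(outdir / "atlas.csv", "map"), velocity)

    velocities = mean_velocity_per_species(velocity, atlas)
    assessment = build_risk_sets(
        prob, statuses, threshold,
        latent_statuses=config.latent_statuses, velocities=velocities,
    )
    outputs = []
    spath = outdir / "risk_sets.csv"
    _write_csv(assessment.table, spath, index=True)
    outputs.append(spath)

    for name in RISK_SET_NAMES:
        grid = richness_map(atlas, assessment.members(name))
        p = outdir / f"richness_{name}.asc"
        write_raster(grid, p)
        outputs.append(p)

    cols = _model_columns(features)
    sub = FeatureMatrix(
        data=features.data[cols], kinds={k: features.kinds[k] for k in cols},
        levels={k: v for k, v in features.levels.items() if k in cols},
    )
    profile = reference_profile(sub)
    for feat in config.attribution_features:
        scores = attribution_scores(forest, sub, feat, profile=profile)
        grid = attribution_map(scores, atlas)
        p = outdir / f"attribution_{feat}.asc"
        write_raster(grid, p)
        outputs.append(p)

    richness = richness_map(atlas, assessment.members("actual_or_potential"))
    class_grid, class_table = overlay_product(velocity, richness)
    opath = outdir / "velocity_richness_overlay.asc"
    write_raster(class_grid, opath)
    ctable = outdir / "overlay_classes.csv"
    _write_csv(class_table, ctable)
    epath = outdir / "velocity_exceedance.csv"
    from .geography import velocity_exceedance

    _write_csv(velocity_exceedance(assessment, thresholds=config.velocity_thresholds), epath)
    return outputs + [opath, ctable, epath]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "extract": stage_extract,
    "fit": stage_fit,
    "evaluate": stage_evaluate,
    "interpret": stage_interpret,
    "map": stage_map,
}


def run_stage(stage: str, config: PipelineConfig, outdir) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    try:
        outputs = _STAGE_FUNCS[stage](config, outdir)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    log.info("stage %s finished in %.1f s (%d outputs)", stage, time.time() - t0, len(outputs))
    return outputs


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run every stage and write a manifest; returns the run directory."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    all_outputs: list[Path] = []
    timings = {}
    for stage in STAGES:
        t0 = time.time()
        all_outputs.extend(run_stage(stage, config, outdir))
        timings[stage] = round(time.time() - t0, 3)
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seeds": config.seeds,
        "stage_seconds": timings,
        "outputs": {
            str(p.relative_to(outdir)): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(all_outputs)
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return outdir
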