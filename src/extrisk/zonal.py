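"""Zonal statistics over species ranges and feature-matrix assembly.

Extrinsic covariates enter the model as summaries of raster layers over
each species' occupied cells: means for continuous layers (cumulative,
minimum and coefficient-of-variation of annual productivity, human
population density, night lights), the modal category for land cover,
and the median latitude/longitude of the range.  Only means of the
continuous layers enter the default feature set; min/max columns can be
appended behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import Grid, RangeAtlas
from .traits import CATEGORICAL_TRAITS, NUMERIC_TRAITS

__all__ = [
    "zonal_stat",
    "zonal_mode",
    "range_median_position",
    "FeatureMatrix",
    "assemble_features",
]

log = logging.getLogger(__name__)

#: raster layer name -> feature column stem used by assemble_features
EXTRINSIC_LAYERS = {
    "cum_productivity": "cum_productivity",
    "min_productivity": "min_productivity",
    "cv_productivity": "cv_productivity",
    "human_density": "human_density",
    "night_lights": "night_lights",
}

#: the model's default feature set: every intrinsic trait plus the
#: mean/modal/positional extrinsic summaries
DEFAULT_FEATURES = [
    "log_range_size",
    "log_body_mass",
    "order_name",
    "mass_specific_production",
    "social_group_size",
    "trophic_group",
    "activity_cycle",
    "home_range",
    "population_density",
    "habitat_mode",
    "landmass_type",
    "mean_cum_productivity",
    "mean_min_productivity",
    "mean_cv_productivity",
    "mean_human_density",
    "mean_night_lights",
    "modal_land_cover",
    "median_lat",
    "median_lon",
]


def zonal_stat(grid: Grid, cells: np.ndarray, stat: str, weights: np.ndarray | None = None) -> float:
    """Summary statistic of a continuous raster over a set of cells.

    ``stat`` is one of ``mean``, ``min``, ``max``.  No-data cells are
    ignored; if every covered cell is no-data the result is NaN
    (missing).  ``weights`` (optional, mean only) weights cells, e.g. by
    cos(latitude) cell area.
    """
    if grid.kind != "continuous":
        raise TypeError("zonal_stat requires a continuous grid; use zonal_mode for categories")
    cells = np.atleast_2d(np.asarray(cells, dtype=np.int64))
    if cells.size == 0:
        raise ValueError("zonal_stat requires at least one cell")
    vals = grid.values[cells[:, 0], cells[:, 1]]
    ok = ~np.isnan(vals)
    if not ok.any():
        return float("nan")
    vals = vals[ok]
    if stat == "mean":
        if weights is not None:
            w = np.asarray(weights, float)[ok]
            return float(np.sum(w * vals) / np.sum(w))
        return float(vals.mean())
    if stat == "min":
        return float(vals.min())
    if stat == "max":
        return float(vals.max())
    raise ValueError(f"unknown zonal statistic {stat!r}")


def zonal_mode(grid: Grid, cells: np.ndarray) -> float:
    """Modal category of a categorical raster over a set of cells.

    Ties are broken toward the smallest category code.  All-no-data
    coverage yields NaN.
    """
    if grid.kind != "categorical":
        raise TypeError("zonal_mode requires a categorical grid")
    cells = np.atleast_2d(np.asarray(cells, dtype=np.int64))
    if cells.size == 0:
        raise ValueError("zonal_mode requires at least one cell")
    vals = grid.values[cells[:, 0], cells[:, 1]]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan")
    codes, counts = np.unique(vals, return_counts=True)
    # np.unique sorts codes ascending, so argmax picks the smallest on ties
    return float(codes[np.argmax(counts)])


def range_median_position(cells: np.ndarray, grid: Grid) -> tuple[float, float]:
    """(median latitude, median longitude) of range cell centers.

    The longitudinal median is computed circularly when the range's
    longitudinal span exceeds 180 degrees, so ranges crossing the
    antimeridian are summarised near +/-180 rather than near 0.
    """
    cells = np.atleast_2d(np.asarray(cells, dtype=np.int64))
    if cells.size == 0:
        raise ValueError("empty range")
    lats = grid.lats[cells[:, 0]]
    lons = grid.lons[cells[:, 1]]
    med_lat = float(np.median(lats))
    if lons.max() - lons.min() > 180.0:
        shifted = np.mod(lons, 360.0)
        med = float(np.median(shifted))
        med_lon = ((med + 180.0) % 360.0) - 180.0
    else:
        med_lon = float(np.median(lons))
    return med_lat, med_lon


@dataclass
class FeatureMatrix:
    """Per-species model features plus a feature dictionary.

    ``data`` is indexed by ``species_id``.  ``kinds`` maps each feature
    to ``"numeric"`` or ``"categorical"``; categorical columns store
    their raw labels, with the level -> integer-code encoding recorded in
    ``levels`` so that unseen levels at prediction time can be treated
    as missing.
    """

    data: pd.DataFrame
    kinds: dict[str, str]
    levels: dict[str, list] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("feature matrix has duplicate species ids")
        unknown = set(self.kinds) - set(self.data.columns)
        if unknown:
            raise ValueError(f"feature dictionary names absent columns: {sorted(unknown)}")
        for name, kind in self.kinds.items():
            if kind == "categorical" and name not in self.levels:
                obs = self.data[name].dropna().unique().tolist()
                self.levels[name] = sorted(obs)

    @property
    def feature_names(self) -> list[str]:
        return list(self.kinds)

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.index)

    def subset(self, ids) -> "FeatureMatrix":
        return FeatureMatrix(
            data=self.data.loc[ids], kinds=dict(self.kinds),
            levels={k: list(v) for k, v in self.levels.items()}, meta=dict(self.meta),
        )

    def to_matrix(self, columns: list[str] | None = None) -> tuple[np.ndarray, list[str], list[str]]:
        """Encode as a float matrix for the forest.

        Categorical labels become integer codes per the stored level
        lists; labels outside a stored list (unseen at training) become
        NaN, i.e. missing.  Returns ``(X, names, kinds)`` where kinds is
        a list of ``"n"``/``"c"`` flags.
        """
        cols = columns if columns is not None else self.feature_names
        n = len(self.data)
        X = np.empty((n, len(cols)), dtype=float)
        kinds = []
        for j, name in enumerate(cols):
            kind = self.kinds[name]
            col = self.data[name]
            if kind == "numeric":
                X[:, j] = pd.to_numeric(col, errors="raise").to_numpy(dtype=float)
                kinds.append("n")
            else:
                lookup = {lev: i for i, lev in enumerate(self.levels[name])}
                X[:, j] = np.array([lookup.get(v, np.nan) if pd.notna(v) else np.nan
                                    for v in col], dtype=float)
                kinds.append("c")
        return X, list(cols), kinds


def assemble_features(
    table: pd.DataFrame,
    rasters: dict[str, Grid],
    atlas: RangeAtlas,
    include_minmax: bool = False,
    area_weighted: bool = False,
) -> FeatureMatrix:
    """Join intrinsic traits with zonal extrinsic covariates.

    Body mass and range size are log10-transformed.  Species present in
    the table but absent from the atlas get missing extrinsic values and
    a logged warning.  Missing intrinsic values are preserved.

    Parameters
    ----------
    include_minmax
        Also append per-layer zonal min/max columns (off by default; the
        default model uses means only).
    area_weighted
        Weight cells by cos(latitude) cell area in zonal means (off by
        default: cells are weighted equally within a range).
    """
    if table["species_id"].duplicated().any():
        raise ValueError("trait table has duplicate species ids")
    df = table.set_index("species_id")
    out = pd.DataFrame(index=df.index)

    out["log_body_mass"] = np.log10(df["body_mass"]) if "body_mass" in df else np.nan
    out["log_range_size"] = np.log10(df["range_size"]) if "range_size" in df else np.nan
    for col in NUMERIC_TRAITS:
        if col in ("body_mass", "range_size"):
            continue
        out[col] = df[col] if col in df else np.nan
    for col in CATEGORICAL_TRAITS:
        out[col] = df[col] if col in df else np.nan

    ext_cols = [f"mean_{stem}" for stem in EXTRINSIC_LAYERS.values()]
    if include_minmax:
        ext_cols += [f"{s}_{stem}" for stem in EXTRINSIC_LAYERS.values() for s in ("min", "max")]
    ext_cols += ["modal_land_cover", "median_lat", "median_lon"]
    for col in ext_cols:
        out[col] = np.nan

    missing_from_atlas = [sid for sid in df.index if sid not in atlas]
    if missing_from_atlas:
        log.warning(
            "%d species in trait table absent from range atlas; extrinsic values left missing: %s",
            len(missing_from_atlas), missing_from_atlas[:10],
        )

    grid = atlas.grid
    for sid in df.index:
        if sid not in atlas:
            continue
        cells = atlas[sid]
        weights = grid.cell_area_km2(cells[:, 0]) if area_weighted else None
        for layer, stem in EXTRINSIC_LAYERS.items():
            if layer not in rasters:
                continue
            g = rasters[layer]
            out.at[sid, f"mean_{stem}"] = zonal_stat(g, cells, "mean", weights=weights)
            if include_minmax:
                out.at[sid, f"min_{stem}"] = zonal_stat(g, cells, "min")
                out.at[sid, f"max_{stem}"] = zonal_stat(g, cells, "max")
        if "land_cover" in rasters:
            out.at[sid, "modal_land_cover"] = zonal_mode(rasters["land_cover"], cells)
        med_lat, med_lon = range_median_position(cells, grid)
        out.at[sid, "median_lat"] = med_lat
        out.at[sid, "median_lon"] = med_lon

    kinds = {}
    for col in out.columns:
        if col in CATEGORICAL_TRAITS or col == "modal_land_cover":
            kinds[col] = "categorical"
        else:
            kinds[col] = "numeric"
    meta = {
        "antimeridian_rule": "circular median longitude when span > 180 degrees",
        "area_weighted": area_weighted,
        "include_minmax": include_minmax,
    }
    return FeatureMatrix(data=out, kinds=kinds, meta=meta)
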