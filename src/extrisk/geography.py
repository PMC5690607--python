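"""Geographic risk products: univariate attribution maps, nested
risk-set richness maps, and climate-velocity exposure.

Risk sets (each a set of species, mapped as per-cell richness):

* **actual** — assessed at risk on the Red List (VU/EN/CR/EW/EX);
* **predicted** — called at risk by the model at the max-kappa
  threshold, Data Deficient species included;
* **dd_predicted** — Data Deficient and predicted at risk;
* **latent** — predicted at risk while holding a status in the latent
  membership set (default {LC, NT, DD});
* **actual_or_potential** — union of actual and predicted.

With the default latent set the memberships nest:
dd_predicted ⊆ latent ⊆ predicted ⊆ actual_or_potential.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cif import ConditionalInferenceForest
from .grids import Grid, RangeAtlas
from .interpret import reference_profile, _profile_matrix
from .traits import AT_RISK_CODES
from .zonal import FeatureMatrix, zonal_stat

__all__ = [
    "RiskAssessment",
    "attribution_scores",
    "attribution_map",
    "build_risk_sets",
    "richness_map",
    "mean_velocity_per_species",
    "velocity_exceedance",
    "overlay_product",
]

log = logging.getLogger(__name__)

DEFAULT_LATENT_STATUSES = frozenset({"LC", "NT", "DD"})
RISK_SET_NAMES = ("actual", "predicted", "dd_predicted", "latent", "actual_or_potential")


@dataclass
class RiskAssessment:
    """Per-species risk calls and set memberships.

    ``table`` is indexed by species_id with columns: probability,
    predicted (bool), redlist_status, one boolean column per risk set,
    and mean_velocity (km/yr, NaN when unavailable).
    """

    table: pd.DataFrame
    threshold: float
    latent_statuses: frozenset = DEFAULT_LATENT_STATUSES
    meta: dict = field(default_factory=dict)

    def members(self, risk_set: str) -> list[str]:
        if risk_set not in RISK_SET_NAMES:
            raise ValueError(f"unknown risk set {risk_set!r}")
        return list(self.table.index[self.table[risk_set]])

    def check_nesting(self) -> None:
        t = self.table
        chains = [("dd_predicted", "latent"), ("latent", "predicted"),
                  ("predicted", "actual_or_potential")]
        for inner, outer in chains:
            if (t[inner] & ~t[outer]).any():
                raise AssertionError(f"risk-set nesting violated: {inner} not within {outer}")


def attribution_scores(
    forest: ConditionalInferenceForest,
    features: FeatureMatrix,
    focal: str,
    profile: dict | None = None,
) -> pd.Series:
    """Per-species risk attributable to one focal variable.

    Every species is scored on the global reference profile with only
    its *observed* focal value substituted (a missing focal value stays
    missing).  Species sharing a focal value therefore share a score.
    """
    if focal not in forest.feature_names:
        raise ValueError(f"focal feature {focal!r} is not in the model")
    if profile is None:
        profile = reference_profile(features)
    n = len(features.data)
    Xp = _profile_matrix(features, profile, n)
    j = forest.feature_names.index(focal)
    observed, _, _ = features.to_matrix([focal])
    Xp[:, j] = observed[:, 0]
    scores = forest.predict_proba(Xp)
    return pd.Series(scores, index=features.data.index, name=f"attribution_{focal}")


def attribution_map(scores: pd.Series, atlas: RangeAtlas, grid: Grid | None = None) -> Grid:
    """Mean per-species attribution score in each occupied cell.

    Cells covered by no species are no-data.  Satisfies the conservation
    identity sum_cells(value * n_species_in_cell) = sum_species(score *
    n_range_cells) exactly.
    """
    grid = grid or atlas.grid
    total = np.zeros(grid.shape)
    count = np.zeros(grid.shape)
    for sid in atlas.species:
        if sid not in scores.index:
            raise ValueError(f"no attribution score for species {sid!r}")
        cells = atlas[sid]
        total[cells[:, 0], cells[:, 1]] += scores.loc[sid]
        count[cells[:, 0], cells[:, 1]] += 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, total / count, np.nan)
    return grid.copy(values=mean, kind="continuous", name=str(scores.name or "attribution"))


def build_risk_sets(
    probabilities: pd.Series,
    statuses: pd.Series,
    threshold: float,
    latent_statuses=DEFAULT_LATENT_STATUSES,
    velocities: pd.Series | None = None,
) -> RiskAssessment:
    """Assemble per-species risk calls and the nested set memberships.

    Species with a missing probability (features never assembled) are
    excluded with a warning.  The classification rule is strict:
    probability > threshold -> predicted at risk.
    """
    latent_statuses = frozenset(latent_statuses)
    probabilities = probabilities.astype(float)
    missing = probabilities.index[probabilities.isna()]
    if len(missing):
        log.warning("excluding %d species with missing probability: %s",
                    len(missing), list(missing[:10]))
        probabilities = probabilities.dropna()
    ids = probabilities.index
    statuses = statuses.reindex(ids)
    predicted = probabilities > threshold
    actual = statuses.isin(AT_RISK_CODES)
    dd = statuses == "DD"
    table = pd.DataFrame({
        "probability": probabilities,
        "predicted": predicted,
        "redlist_status": statuses,
        "actual": actual,
        "dd_predicted": dd & predicted,
        "latent": statuses.isin(latent_statuses) & predicted,
        "actual_or_potential": actual | predicted,
    }, index=ids)
    table["mean_velocity"] = velocities.reindex(ids) if velocities is not None else np.nan
    assessment = RiskAssessment(
        table=table, threshold=threshold, latent_statuses=latent_statuses,
    )
    if latent_statuses >= {"DD"}:
        assessment.check_nesting()
    return assessment


def richness_map(atlas: RangeAtlas, species_subset, grid: Grid | None = None) -> Grid:
    """Per-cell count of subset species whose ranges cover the cell."""
    grid = grid or atlas.grid
    subset = list(species_subset)
    unknown = [sid for sid in subset if sid not in atlas]
    if unknown:
        raise ValueError(f"species not in atlas: {unknown[:10]}")
    counts = np.zeros(grid.shape)
    for sid in subset:
        cells = atlas[sid]
        counts[cells[:, 0], cells[:, 1]] += 1.0
    return grid.copy(values=counts, kind="continuous", name="richness")


def mean_velocity_per_species(velocity: Grid, atlas: RangeAtlas) -> pd.Series:
    """Mean climate-change velocity (km/yr) within each species' range."""
    if not velocity.is_compatible(atlas.grid):
        raise ValueError("velocity grid is not co-registered with the atlas grid")
    vals = {sid: zonal_stat(velocity, atlas[sid], "mean") for sid in atlas.species}
    return pd.Series(vals, name="mean_velocity")


def velocity_exceedance(
    assessment: RiskAssessment,
    thresholds=(0.5, 1.0),
) -> pd.DataFrame:
    """Count and fraction of each risk set's species at or above each
    velocity threshold (rule: mean range velocity >= threshold km/yr)."""
    rows = []
    t = assessment.table
    for name in RISK_SET_NAMES:
        members = t[t[name]]
        vel = members["mean_velocity"].dropna()
        for thr in thresholds:
            count = int((vel >= thr).sum())
            rows.append({
                "risk_set": name,
                "threshold_km_per_yr": float(thr),
                "n_members": int(len(members)),
                "n_with_velocity": int(len(vel)),
                "n_exceeding": count,
                "fraction": count / len(vel) if len(vel) else float("nan"),
            })
    return pd.DataFrame(rows)


def _tercile_class(values: np.ndarray, valid: np.ndarray, breaks=None) -> np.ndarray:
    """0/1/2 class per cell from tercile (or supplied) breaks."""
    out = np.full(values.shape, -1, dtype=int)
    v = values[valid]
    if breaks is None:
        breaks = np.quantile(v, [1 / 3, 2 / 3]) if v.size else np.array([0.0, 0.0])
    cls = np.digitize(v, breaks, right=True)
    out[valid] = cls
    return out


def overlay_product(velocity: Grid, richness: Grid, velocity_breaks=None, richness_breaks=None):
    """Joint velocity x richness overlay.

    Returns ``(class_grid, table)``: a categorical grid of bivariate
    class codes ``3 * velocity_class + richness_class`` (classes 0..2
    from tercile breaks of each layer over co-valid cells) and a tidy
    per-class cell count table.  Class counts sum to the number of
    co-valid cells.
    """
    if not velocity.is_compatible(richness):
        raise ValueError("overlay requires co-registered grids")
    valid = ~np.isnan(velocity.values) & ~np.isnan(richness.values)
    vc = _tercile_class(velocity.values, valid, velocity_breaks)
    rc = _tercile_class(richness.values, valid, richness_breaks)
    code = np.where(valid, 3 * vc + rc, np.nan).astype(float)
    class_grid = velocity.copy(values=code, kind="categorical", name="velocity_richness_class")
    labels = ["low", "mid", "high"]
    rows = []
    for v in range(3):
        for r in range(3):
            rows.append({
                "class_code": 3 * v + r,
                "velocity_class": labels[v],
                "richness_class": labels[r],
                "n_cells": int(np.sum(valid & (vc == v) & (rc == r))),
            })
    return class_grid, pd.DataFrame(rows)
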