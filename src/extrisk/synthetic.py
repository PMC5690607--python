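"""Synthetic world generator with known risk-generating truth.

Emulates the statistical structure of a global species risk analysis:

* raster covariates on a quarter-degree lat/lon grid — cumulative annual
  productivity falling with |latitude|, seasonality (CV of productivity)
  rising with |latitude|, minimum productivity derived from the two,
  human population density as a sum of Gaussian hotspots, night lights
  tracking human density, a spatially autocorrelated categorical land
  cover, and a smooth positive climate-velocity field;
* species with log-normal range sizes (disc-shaped ranges around random
  centroids) and log-normal body masses with taxonomic-order offsets,
  plus allometrically plausible secondary traits;
* a binary at-risk label drawn from a logistic model on a named subset
  of standardized features, with the intercept bisected so realized
  prevalence matches a target;
* a fraction of species masked as Data Deficient, and per-trait missing
  values in the public table.

Everything is a pure function of (config, seed), and the generating
truth (true label, linear predictor, coefficients) is returned separately
from the table handed to the pipeline, so downstream stages cannot leak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grids import Grid, RangeAtlas
from .zonal import FeatureMatrix, assemble_features

__all__ = ["WorldConfig", "SyntheticData", "make_world", "make_species", "assign_risk", "simulate"]

#: default true risk coefficients on standardized features; range size is
#: the dominant (negative) driver, then body mass (+), human density (+)
#: and seasonality (-), mirroring the headline ordering of documented
#: mammal risk correlates
DEFAULT_BETA = {
    "log_range_size": -2.4,
    "log_body_mass": 1.2,
    "mean_human_density": 1.2,
    "mean_cv_productivity": -0.9,
}

DEFAULT_MISSINGNESS = {
    "body_mass": 0.10,
    "mass_specific_production": 0.20,
    "social_group_size": 0.30,
    "home_range": 0.40,
    "population_density": 0.30,
    "activity_cycle": 0.10,
    "habitat_mode": 0.05,
}

TROPHIC_GROUPS = ("herbivore", "omnivore", "carnivore")
ACTIVITY_CYCLES = ("nocturnal", "crepuscular", "diurnal")
HABITAT_MODES = ("terrestrial", "arboreal", "fossorial", "semiaquatic")


@dataclass
class WorldConfig:
    """Generating conditions of the synthetic world."""

    # grid
    resolution: float = 0.25
    lon_min: float = -180.0
    lon_max: float = 180.0
    lat_min: float = -75.0
    lat_max: float = 75.0
    # species
    n_species: int = 2000
    n_orders: int = 8
    range_lognorm_mu: float = 12.0   # ln km^2; median ~1.6e5 km^2
    range_lognorm_sigma: float = 2.0
    mass_lognorm_mu: float = 4.6     # ln grams; median ~100 g
    mass_lognorm_sigma: float = 2.3
    order_offset_sd: float = 1.2
    # human-density hotspots
    n_hotspots: int = 12
    hotspot_amplitude_mu: float = 6.7   # ln people/km^2 at peak (~800)
    hotspot_amplitude_sigma: float = 0.8
    hotspot_decay_min_deg: float = 4.0
    hotspot_decay_max_deg: float = 14.0
    human_background: float = 2.0
    # productivity gradient
    productivity_scale: float = 100.0
    productivity_floor: float = 0.15
    productivity_noise: float = 0.3
    seasonality_base: float = 0.1
    seasonality_gain: float = 1.1
    seasonality_exponent: float = 1.3
    seasonality_noise: float = 0.15
    # land cover / velocity
    n_land_cover: int = 8
    field_smooth_cells: float = 10.0
    velocity_log_mu: float = -0.8    # ln km/yr; median ~0.45
    velocity_log_sigma: float = 0.8
    # risk generation
    beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    target_prevalence: float = 0.25
    prevalence_tolerance: float = 0.01
    dd_fraction: float = 0.10
    missingness: dict = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ValueError("degenerate grid extent")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        for name, p in (("target_prevalence", self.target_prevalence),
                        ("dd_fraction", self.dd_fraction)):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        for trait, frac in self.missingness.items():
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"missingness[{trait}] must be in [0, 1]")
        if self.range_lognorm_sigma <= 0 or self.mass_lognorm_sigma <= 0:
            raise ValueError("log-normal sigma must be positive")

    def grid_shape(self) -> tuple[int, int]:
        n_rows = int(round((self.lat_max - self.lat_min) / self.resolution))
        n_cols = int(round((self.lon_max - self.lon_min) / self.resolution))
        return n_rows, n_cols

    def empty_grid(self, kind: str = "continuous", name: str = "") -> Grid:
        n_rows, n_cols = self.grid_shape()
        return Grid(
            values=np.zeros((n_rows, n_cols)), resolution=self.resolution,
            origin=(self.lon_min, self.lat_max), kind=kind, name=name,
        )


def _smooth_field(shape, sigma, rng) -> np.ndarray:
    """Standardized spatially autocorrelated Gaussian field (wrap in lon)."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode=["nearest", "wrap"])
    return (f - f.mean()) / max(f.std(), 1e-12)


def make_world(config: WorldConfig, seed: int | None = None) -> dict[str, Grid]:
    """Generate the raster covariate stack."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    template = config.empty_grid()
    n_rows, n_cols = template.shape
    lats = template.lats
    lat_frac = (np.abs(lats) / max(abs(config.lat_min), abs(config.lat_max)))[:, None]
    sm = config.field_smooth_cells

    f_prod = _smooth_field((n_rows, n_cols), sm, rng)
    f_seas = _smooth_field((n_rows, n_cols), sm, rng)
    f_lights = _smooth_field((n_rows, n_cols), sm, rng)
    f_vel = _smooth_field((n_rows, n_cols), sm, rng)

    cum = config.productivity_scale * (
        config.productivity_floor
        + (1 - config.productivity_floor) * np.cos(np.radians(lats))[:, None] ** 2
    ) * np.exp(config.productivity_noise * f_prod)

    cv = np.clip(
        config.seasonality_base
        + config.seasonality_gain * lat_frac ** config.seasonality_exponent
        + config.seasonality_noise * f_seas,
        0.02, 1.5,
    )
    minp = np.clip(cum * (1.0 - np.clip(cv, 0.0, 1.0)), 0.0, None)

    lons = template.lons
    human = np.full((n_rows, n_cols), config.human_background, dtype=float)
    for _ in range(config.n_hotspots):
        c_lat = rng.uniform(config.lat_min, config.lat_max)
        c_lon = rng.uniform(config.lon_min, config.lon_max)
        amp = np.exp(rng.normal(config.hotspot_amplitude_mu, config.hotspot_amplitude_sigma))
        decay = rng.uniform(config.hotspot_decay_min_deg, config.hotspot_decay_max_deg)
        dlon = np.abs(lons[None, :] - c_lon)
        dlon = np.minimum(dlon, 360.0 - dlon)
        d2 = (lats[:, None] - c_lat) ** 2 + dlon ** 2
        human += amp * np.exp(-d2 / (2.0 * decay ** 2))

    lights = np.clip(8.0 * np.log1p(human) + 2.0 * f_lights, 0.0, None)

    cover_fields = np.stack([
        _smooth_field((n_rows, n_cols), sm, rng) + rng.normal(0, 0.25)
        for _ in range(config.n_land_cover)
    ])
    land_cover = np.argmax(cover_fields, axis=0).astype(float)

    velocity = np.exp(config.velocity_log_mu + config.velocity_log_sigma * f_vel)

    def grid(vals, kind, name):
        return template.copy(values=vals, kind=kind, name=name)

    return {
        "cum_productivity": grid(cum, "continuous", "cum_productivity"),
        "min_productivity": grid(minp, "continuous", "min_productivity"),
        "cv_productivity": grid(cv, "continuous", "cv_productivity"),
        "human_density": grid(human, "continuous", "human_density"),
        "night_lights": grid(lights, "continuous", "night_lights"),
        "land_cover": grid(land_cover, "categorical", "land_cover"),
        "velocity": grid(velocity, "continuous", "velocity"),
    }


def _disc_cells(grid: Grid, row0: int, col0: int, n_cells: int) -> np.ndarray:
    """The n_cells grid cells nearest (row0, col0) in great-circle-ish
    cell units (columns shortened by cos latitude; longitude wraps)."""
    n_rows, n_cols = grid.shape
    n_cells = min(n_cells, n_rows * n_cols)
    cos0 = max(np.cos(np.radians(grid.lats[row0])), 0.05)
    half_r = int(np.ceil(np.sqrt(n_cells / np.pi))) + 2
    half_c = int(np.ceil(half_r / cos0)) + 2
    rows = np.arange(max(0, row0 - half_r), min(n_rows, row0 + half_r + 1))
    cols = col0 + np.arange(-min(half_c, n_cols // 2), min(half_c, n_cols // 2) + 1)
    cols_wrapped = np.mod(cols, n_cols)
    dr = (rows - row0)[:, None].astype(float)
    dc = (cols - col0)[None, :].astype(float) * cos0
    d2 = dr ** 2 + dc ** 2
    rr, cc = np.meshgrid(rows, cols_wrapped, indexing="ij")
    flat = np.argsort(d2.ravel(), kind="stable")[:n_cells]
    return np.column_stack([rr.ravel()[flat], cc.ravel()[flat]]).astype(np.int64)


def make_species(
    config: WorldConfig, world: dict[str, Grid], seed: int | None = None
) -> tuple[pd.DataFrame, RangeAtlas]:
    """Generate the intrinsic trait table (complete, pre-missingness) and
    the range atlas.

    Ranges are discs of cells around centroids drawn cos(latitude)-
    uniformly over the grid, with areas from the range-size log-normal
    truncated to the grid; ``range_size`` is cell count times the cell
    area at the centroid latitude.
    """
    config.validate()
    rng = np.random.default_rng((config.seed if seed is None else seed))
    grid = next(iter(world.values()))
    n_rows, n_cols = grid.shape
    n = config.n_species

    order_names = [f"ORD{i + 1:02d}" for i in range(config.n_orders)]
    order_offsets = rng.normal(0.0, config.order_offset_sd, size=config.n_orders)
    orders = rng.integers(0, config.n_orders, size=n)

    log_mass = rng.normal(
        config.mass_lognorm_mu + order_offsets[orders], config.mass_lognorm_sigma
    )
    body_mass = np.exp(log_mass)

    # centroids: uniform on the sphere within the extent
    row_weights = np.cos(np.radians(grid.lats))
    row_weights = row_weights / row_weights.sum()
    rows0 = rng.choice(n_rows, size=n, p=row_weights)
    cols0 = rng.integers(0, n_cols, size=n)

    target_area = np.exp(rng.normal(config.range_lognorm_mu, config.range_lognorm_sigma, size=n))
    records = []
    cells: dict[str, np.ndarray] = {}
    for i in range(n):
        sid = f"SP{i + 1:05d}"
        cell_area = float(grid.cell_area_km2(int(rows0[i])))
        n_cells = max(1, int(round(target_area[i] / max(cell_area, 1e-9))))
        arr = _disc_cells(grid, int(rows0[i]), int(cols0[i]), n_cells)
        cells[sid] = arr
        range_size = len(arr) * cell_area
        mass = body_mass[i]
        records.append({
            "species_id": sid,
            "order_name": order_names[orders[i]],
            "body_mass": mass,
            "range_size": range_size,
            # speed of life history: allometric ~ mass^-0.25 with noise
            "mass_specific_production": float(np.exp(
                1.5 - 0.25 * np.log(mass) + rng.normal(0, 0.3))),
            "social_group_size": float(max(1.0, np.round(np.exp(rng.normal(1.0, 1.0))))),
            "trophic_group": TROPHIC_GROUPS[rng.choice(3, p=[0.45, 0.30, 0.25])],
            "activity_cycle": ACTIVITY_CYCLES[rng.choice(3, p=[0.45, 0.20, 0.35])],
            # home range grows, population density falls, with body mass
            "home_range": float(np.exp(-6.0 + 0.9 * np.log(mass) + rng.normal(0, 1.0))),
            "population_density": float(np.exp(9.5 - 0.75 * np.log(mass) + rng.normal(0, 0.8))),
            "habitat_mode": HABITAT_MODES[rng.choice(4, p=[0.55, 0.25, 0.12, 0.08])],
            "landmass_type": ("island" if range_size < 5e4 and rng.random() < 0.6
                              else ("both" if rng.random() < 0.15 else "mainland")),
            "redlist_status": None,
        })
    traits = pd.DataFrame.from_records(records)
    atlas = RangeAtlas(cells=cells, grid=grid)
    return traits, atlas


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def assign_risk(
    config: WorldConfig, features: FeatureMatrix, seed: int | None = None
) -> tuple[pd.Series, pd.DataFrame, dict]:
    """Draw at-risk labels from the logistic generating model.

    P(at risk) = sigmoid(intercept + beta . z), with z the named features
    standardized over species and the intercept tuned by bisection so the
    mean probability matches the target prevalence.  At-risk species get
    a uniform status from {VU, EN, CR}, others from {LC, NT}; a DD
    fraction is then masked uniformly at random.  Returns (statuses,
    ground-truth table, info dict); the ground truth never enters the
    public trait table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    missing_features = [nm for nm in config.beta if nm not in features.kinds]
    if missing_features:
        raise ValueError(f"beta names features absent from the matrix: {missing_features}")

    n = len(features.data)
    lp = np.zeros(n)
    for name, coef in config.beta.items():
        col = features.data[name].to_numpy(dtype=float)
        mu = np.nanmean(col)
        sd = np.nanstd(col)
        z = (np.nan_to_num(col, nan=mu) - mu) / max(sd, 1e-12)
        lp += coef * z

    target = config.target_prevalence
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if _sigmoid(lp + mid).mean() < target:
            lo = mid
        else:
            hi = mid
    intercept = (lo + hi) / 2.0
    prob = _sigmoid(lp + intercept)

    at_risk = rng.random(n) < prob
    codes = np.where(
        at_risk,
        rng.choice(["VU", "EN", "CR"], size=n),
        rng.choice(["LC", "NT"], size=n),
    )
    dd_mask = rng.random(n) < config.dd_fraction
    statuses = pd.Series(np.where(dd_mask, "DD", codes), index=features.data.index,
                         name="redlist_status")
    groundtruth = pd.DataFrame({
        "true_at_risk": at_risk.astype(int),
        "probability": prob,
        "linear_predictor": lp + intercept,
        "masked_dd": dd_mask,
    }, index=features.data.index)
    info = {
        "beta": dict(config.beta),
        "intercept": float(intercept),
        "target_prevalence": target,
        "realized_prevalence": float(at_risk.mean()),
        "mean_probability": float(prob.mean()),
    }
    return statuses, groundtruth, info


@dataclass
class SyntheticData:
    """A full synthetic study: rasters, public trait table, atlas, and
    the private generating truth."""

    config: WorldConfig
    rasters: dict[str, Grid]
    traits: pd.DataFrame       # public table (missingness + DD applied)
    atlas: RangeAtlas
    features: FeatureMatrix    # complete features used by the generator
    groundtruth: pd.DataFrame  # never handed to the pipeline
    info: dict


def simulate(config: WorldConfig | None = None, seed: int | None = None) -> SyntheticData:
    """Generate a complete synthetic study, a pure function of
    (config, seed)."""
    config = config or WorldConfig()
    config.validate()
    base = config.seed if seed is None else seed
    ss = np.random.SeedSequence(base)
    s_world, s_species, s_risk, s_mask = [
        int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(4)
    ]

    rasters = make_world(config, seed=s_world)
    traits, atlas = make_species(config, rasters, seed=s_species)
    features = assemble_features(traits, rasters, atlas)
    statuses, groundtruth, info = assign_risk(config, features, seed=s_risk)

    public = traits.copy()
    public["redlist_status"] = statuses.to_numpy()
    rng = np.random.default_rng(s_mask)
    for trait, frac in config.missingness.items():
        if trait not in public.columns or frac <= 0:
            continue
        mask = rng.random(len(public)) < frac
        public.loc[mask, trait] = np.nan

    return SyntheticData(
        config=config, rasters=rasters, traits=public, atlas=atlas,
        features=features, groundtruth=groundtruth, info=info,
    )
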