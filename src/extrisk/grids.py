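"""Georeferenced analysis grids and species range atlases.

A :class:`Grid` is a regular latitude/longitude lattice (row 0 is the
northernmost row, row-major storage) whose cell values are either real
numbers (``kind="continuous"``) or integer category codes
(``kind="categorical"``).  No-data cells are stored as NaN so they are
always distinguishable from 0.  Grids round-trip through the ESRI ASCII
grid format, the plain-text raster dialect used throughout the package.

A :class:`RangeAtlas` maps species identifiers to the sets of grid cells
their geographic ranges occupy, at the analysis resolution (0.25 degrees
by default).  Atlases can be read from per-species cell lists (CSV) or
rasterized from GeoJSON polygons by cell-center inclusion.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Grid", "RangeAtlas", "read_raster", "write_raster", "read_range_atlas"]

#: kilometres per degree of latitude (spherical mean-radius Earth)
KM_PER_DEGREE = 111.19492664455873

# tiny offset used to resolve polygon-boundary ties toward +lon / -lat,
# giving a single unambiguous half-open rasterization rule
_EDGE_EPS = 1e-9


@dataclass
class Grid:
    """A regular lat/lon raster with NaN as the no-data marker.

    Parameters
    ----------
    values
        ``(n_rows, n_cols)`` array.  Row 0 is the northernmost row.
    resolution
        Cell size in degrees (square cells).
    origin
        ``(lon, lat)`` of the *outer* north-west corner of cell (0, 0).
    kind
        ``"continuous"`` or ``"categorical"``.  Categorical grids hold
        integer category codes (stored as floats so NaN can mark no-data).
    """

    values: np.ndarray
    resolution: float = 0.25
    origin: tuple[float, float] = (-180.0, 90.0)
    kind: str = "continuous"
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be a 2-D array")
        if self.resolution <= 0:
            raise ValueError("grid resolution must be positive")
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown grid kind {self.kind!r}")

    # -- geometry ---------------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def lats(self) -> np.ndarray:
        """Latitudes of cell centers, north to south."""
        lat0 = self.origin[1] - self.resolution / 2.0
        return lat0 - self.resolution * np.arange(self.n_rows)

    @property
    def lons(self) -> np.ndarray:
        """Longitudes of cell centers, west to east."""
        lon0 = self.origin[0] + self.resolution / 2.0
        return lon0 + self.resolution * np.arange(self.n_cols)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the center of cell ``(row, col)``."""
        return (float(self.lons[col]), float(self.lats[row]))

    def cell_area_km2(self, row: int | np.ndarray) -> np.ndarray:
        """Approximate cell area (km^2) at the latitude of ``row``."""
        lat = self.lats[row]
        return (KM_PER_DEGREE * self.resolution) ** 2 * np.cos(np.radians(lat))

    # -- values -----------------------------------------------------------

    @property
    def nodata_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def is_compatible(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.resolution, other.resolution)
            and math.isclose(self.origin[0], other.origin[0])
            and math.isclose(self.origin[1], other.origin[1])
        )

    def copy(self, values: np.ndarray | None = None, **kwargs) -> "Grid":
        """A copy of this grid, optionally with new cell values."""
        out = Grid(
            values=self.values.copy() if values is None else np.asarray(values, float),
            resolution=self.resolution,
            origin=self.origin,
            kind=kwargs.pop("kind", self.kind),
            name=kwargs.pop("name", self.name),
        )
        if out.shape != self.shape:
            raise ValueError("replacement values have a different shape")
        return out


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def write_raster(grid: Grid, path, nodata: float = -9999.0) -> None:
    """Write a grid as an ESRI ASCII raster.

    Values are formatted with ``%.17g`` so that a write/read round trip
    reproduces them bit-exactly.
    """
    vals = grid.values.copy()
    vals[np.isnan(vals)] = nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.origin[0]!r}\n")
        fh.write(f"yllcorner {grid.origin[1] - grid.n_rows * grid.resolution!r}\n")
        fh.write(f"cellsize {grid.resolution!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in vals:
            fh.write(" ".join("%.17g" % v for v in row))
            fh.write("\n")


def read_raster(path, kind: str = "continuous", name: str = "") -> Grid:
    """Read an ESRI ASCII raster.

    The format itself carries no continuous/categorical flag, so the
    caller declares the ``kind``.
    """
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
                       "yllcenter", "cellsize", "nodata_value"):
                if len(parts) != 2:
                    raise ValueError(f"malformed header line: {line.strip()!r}")
                header[key] = float(parts[1])
            else:
                rows.append(np.array(parts, dtype=float))
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise ValueError(f"ASCII grid header is missing {req!r}")
    if "xllcenter" in header or "yllcenter" in header:
        raise ValueError("cell-center referenced ASCII grids are not supported")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    values = np.vstack(rows) if rows else np.empty((0, n_cols))
    if values.shape != (n_rows, n_cols):
        raise ValueError(
            f"grid body has shape {values.shape}, header declares {(n_rows, n_cols)}"
        )
    nodata = header.get("nodata_value")
    if nodata is not None:
        values[values == nodata] = np.nan
    res = header["cellsize"]
    origin = (header.get("xllcorner", 0.0), header.get("yllcorner", 0.0) + n_rows * res)
    return Grid(values=values, resolution=res, origin=origin, kind=kind, name=name)


# ---------------------------------------------------------------------------
# Range atlases


@dataclass
class RangeAtlas:
    """Species ranges as sets of occupied cells on a reference grid.

    ``cells`` maps ``species_id`` to an ``(k, 2)`` integer array of
    ``(row, col)`` indices.  Every species must occupy at least one cell
    and every index must lie on the reference grid.
    """

    cells: dict[str, np.ndarray]
    grid: Grid
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for sid, arr in self.cells.items():
            arr = np.atleast_2d(np.asarray(arr, dtype=np.int64))
            if arr.size == 0:
                raise ValueError(f"species {sid!r} has an empty range")
            if arr.shape[1] != 2:
                raise ValueError(f"species {sid!r}: cells must be (row, col) pairs")
            if (
                arr[:, 0].min() < 0
                or arr[:, 0].max() >= self.grid.n_rows
                or arr[:, 1].min() < 0
                or arr[:, 1].max() >= self.grid.n_cols
            ):
                raise ValueError(f"species {sid!r} has cells outside the grid")
            clean[sid] = arr
        self.cells = clean

    @property
    def species(self) -> list[str]:
        return list(self.cells)

    def __len__(self) -> int:
        return len(self.cells)

    def __contains__(self, sid: str) -> bool:
        return sid in self.cells

    def __getitem__(self, sid: str) -> np.ndarray:
        return self.cells[sid]

    def n_cells(self, sid: str) -> int:
        return len(self.cells[sid])

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("species_id,row,col\n")
            for sid, arr in self.cells.items():
                for r, c in arr:
                    fh.write(f"{sid},{r},{c}\n")

    @classmethod
    def from_csv(cls, path, grid: Grid) -> "RangeAtlas":
        import pandas as pd

        df = pd.read_csv(path, dtype={"species_id": str})
        for col in ("species_id", "row", "col"):
            if col not in df.columns:
                raise ValueError(f"range atlas CSV is missing column {col!r}")
        cells = {
            str(sid): sub[["row", "col"]].to_numpy(dtype=np.int64)
            for sid, sub in df.groupby("species_id", sort=True)
        }
        return cls(cells=cells, grid=grid)

    @classmethod
    def from_geojson(cls, path, grid: Grid) -> "RangeAtlas":
        """Rasterize GeoJSON (Multi)Polygon features by cell-center inclusion.

        Each feature must carry a ``species_id`` property.  A cell belongs
        to a species when the polygon covers the cell center; boundary
        ties are resolved toward +lon / -lat by testing a point nudged an
        infinitesimal step in that direction.  A polygon covering no cell
        center is an error naming the species.
        """
        from shapely.geometry import shape
        from shapely.prepared import prep

        with open(path) as fh:
            gj = json.load(fh)
        features = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
        lats, lons = grid.lats, grid.lons
        cells: dict[str, list[np.ndarray]] = {}
        from shapely.geometry import Point

        for feat in features:
            props = feat.get("properties") or {}
            sid = props.get("species_id")
            if sid is None:
                raise ValueError("GeoJSON feature is missing a species_id property")
            geom = shape(feat["geometry"])
            minx, miny, maxx, maxy = geom.bounds
            col_sel = np.nonzero((lons >= minx - grid.resolution) & (lons <= maxx + grid.resolution))[0]
            row_sel = np.nonzero((lats >= miny - grid.resolution) & (lats <= maxy + grid.resolution))[0]
            prepared = prep(geom)
            hits = [
                (r, c)
                for r in row_sel
                for c in col_sel
                if prepared.covers(Point(lons[c] + _EDGE_EPS, lats[r] - _EDGE_EPS))
            ]
            if not hits:
                raise ValueError(f"range polygon for species {sid!r} covers no cell center")
            cells.setdefault(str(sid), []).append(np.array(hits, dtype=np.int64))
        merged = {
            sid: np.unique(np.vstack(parts), axis=0) for sid, parts in cells.items()
        }
        return cls(cells=merged, grid=grid)


def read_range_atlas(path, grid: Grid) -> RangeAtlas:
    """Read a range atlas from GeoJSON polygons or a species/row/col CSV."""
    path = str(path)
    if path.endswith((".geojson", ".json")):
        return RangeAtlas.from_geojson(path, grid)
    return RangeAtlas.from_csv(path, grid)
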