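"""Small matplotlib helpers for the model's standard displays."""

from __future__ import annotations

import numpy as np

from .grids import Grid
from .interpret import ImportanceTable, PDCurve


def plot_partial_dependence(curve: PDCurve, ax=None):
    """Risk probability against one feature (line for numeric, bars for
    categorical)."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    if curve.kind == "numeric":
        ax.plot(curve.grid, curve.probability, lw=2)
    else:
        ax.bar([str(v) for v in curve.labels], curve.probability)
        ax.tick_params(axis="x", rotation=45)
    ax.set_xlabel(curve.feature)
    ax.set_ylabel("P(at risk)")
    ax.set_ylim(0, 1)
    return ax


def plot_importance(imp: ImportanceTable, ax=None, top: int | None = None):
    """Horizontal bar chart of permutation importance, best first."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    tab = imp.table if top is None else imp.table.head(top)
    ax.barh(tab["feature"][::-1], tab["importance"][::-1], xerr=tab["sd"][::-1])
    ax.set_xlabel("mean decrease in out-of-subsample accuracy")
    return ax


def plot_grid(grid: Grid, ax=None, cmap="viridis", **imshow_kwargs):
    """Render a grid in geographic coordinates (no-data transparent)."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    lon0, lat0 = grid.origin
    extent = (lon0, lon0 + grid.n_cols * grid.resolution,
              lat0 - grid.n_rows * grid.resolution, lat0)
    masked = np.ma.masked_invalid(grid.values)
    im = ax.imshow(masked, extent=extent, origin="upper", cmap=cmap, **imshow_kwargs)
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    if grid.name:
        ax.set_title(grid.name)
    return im
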