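"""Static map rendering of hot/cold-spot grids.

Replaces interactive cartography with a minimal matplotlib layer: cells are
drawn in projected coordinates, coloured by Gi* z-score with the usual
red (hot) / blue (cold) diverging scheme.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Rectangle

from .hotspot import GiStarResult


def plot_hotspots(result: GiStarResult, path: str | Path, title: str = "") -> Path:
    """Render Gi* z-scores per cell to a PNG; returns the written path."""
    spec = result.grid.spec
    fig, ax = plt.subplots(figsize=(8, 6))
    vmax = max(2.576, float(abs(result.z).max()) or 1.0)
    cmap = plt.get_cmap("RdBu_r")
    for (ix, iy), z in zip(result.cells, result.z):
        color = cmap(0.5 + 0.5 * z / vmax)
        ax.add_patch(Rectangle(
            (spec.x0 + ix * spec.cell_size_m, spec.y0 + iy * spec.cell_size_m),
            spec.cell_size_m, spec.cell_size_m,
            facecolor=color, edgecolor="none",
        ))
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.set_xlabel(f"easting [m] ({spec.crs.name})")
    ax.set_ylabel("northing [m]")
    ax.set_title(title or "Gi* stress hot/cold spots")
    sm = plt.cm.ScalarMappable(cmap=cmap, norm=plt.Normalize(-vmax, vmax))
    fig.colorbar(sm, ax=ax, label="Gi* z")
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
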