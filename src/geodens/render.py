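"""Cosmetic map rendering. Never load-bearing: failures warn, not raise."""

from __future__ import annotations

import logging
import warnings

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.colors import BoundaryNorm, ListedColormap

log = logging.getLogger(__name__)

__all__ = ["render"]


def render(surface, path, region=None, overlay_points=None, title: str | None = None) -> bool:
    """Save a PNG heatmap of a density or comparison surface.

    Indicator surfaces get a categorical three-color rendering; anything
    else a continuous colormap. ``overlay_points`` is an optional
    iterable of (x, y) markers (e.g. recruitment venues). Returns True on
    success; rendering problems warn and return False.
    """
    try:
        grid = surface.grid
        extent = (
            grid.xll,
            grid.xll + grid.ncols * grid.cell_size,
            grid.yll,
            grid.yll + grid.nrows * grid.cell_size,
        )
        fig, ax = plt.subplots(figsize=(6, 6))
        kind = getattr(surface, "kind", "density")
        if kind == "indicator_difference":
            cmap = ListedColormap(["#2c7bb6", "#ffffff", "#d7191c"])
            norm = BoundaryNorm([-1.5, -0.5, 0.5, 1.5], cmap.N)
            im = ax.imshow(surface.values, extent=extent, cmap=cmap, norm=norm)
            fig.colorbar(im, ax=ax, ticks=[-1, 0, 1], shrink=0.8)
        else:
            im = ax.imshow(surface.values, extent=extent, cmap="viridis")
            fig.colorbar(im, ax=ax, shrink=0.8, label="users / sq mi")
        if region is not None:
            bx, by = region.polygon.exterior.xy
            ax.plot(bx, by, color="0.3", lw=1)
        if overlay_points is not None:
            pts = list(overlay_points)
            if pts:
                ax.scatter(
                    [p[0] for p in pts], [p[1] for p in pts],
                    marker="^", s=40, color="green", edgecolor="black", zorder=3,
                )
        ax.set_xlabel("x (miles)")
        ax.set_ylabel("y (miles)")
        if title:
            ax.set_title(title)
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return True
    except Exception as exc:  # pragma: no cover - cosmetic path
        warnings.warn(f"rendering failed: {exc}", stacklevel=2)
        return False
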