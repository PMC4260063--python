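"""Raster map algebra for comparing density surfaces.

Three complementary comparisons of two co-registered density surfaces:
the cellwise absolute difference (null value 0), the cellwise ratio
(null value 1), and a three-valued indicator difference contrasting each
surface's own extreme-density areas,

    I(a > mean_a + n*sd_a) - I(b > mean_b + n*sd_b)  in {-1, 0, 1},

where mean and sd are taken over the surface's own cells. The indicator
map highlights where one group's density is extreme *for that group*
while the other's is not, regardless of absolute magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .density import DensitySurface, GridSpec
from .errors import EmptySurfaceError, IncompatibleGridsError

__all__ = [
    "SurfaceStats",
    "ComparisonSurface",
    "surface_stats",
    "surface_difference",
    "surface_ratio",
    "extreme_mask",
    "indicator_difference",
]


@dataclass(frozen=True)
class SurfaceStats:
    """Mean, population SD and the mean + n_sd * sd extreme threshold."""

    mean: float
    sd: float
    n_sd: float
    n_cells: int

    @property
    def threshold(self) -> float:
        return self.mean + self.n_sd * self.sd


@dataclass
class ComparisonSurface:
    """A raster derived from one or two density surfaces."""

    grid: GridSpec
    values: np.ndarray
    kind: str  # difference | ratio | indicator_difference | mask
    parent_stats: tuple[SurfaceStats, ...] = ()

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.nrows, self.grid.ncols):
            raise EmptySurfaceError("values shape does not match grid")


def _check_grids(a: DensitySurface, b: DensitySurface) -> None:
    if a.grid != b.grid:
        raise IncompatibleGridsError(f"grids differ: {a.grid} vs {b.grid}")


def surface_stats(surface: DensitySurface, n_sd: float = 2.0) -> SurfaceStats:
    """Cell mean and population SD over non-NODATA cells, plus threshold.

    The threshold ``mean + n_sd * sd`` marks a surface's own
    extreme-density cells; e.g. a surface with mean 14 and SD 7 users per
    square mile has a two-SD threshold of 28.
    """
    vals = surface.values[~np.isnan(surface.values)]
    if vals.size == 0:
        raise EmptySurfaceError("surface has no non-NODATA cells")
    return SurfaceStats(mean=float(vals.mean()), sd=float(vals.std()), n_sd=float(n_sd), n_cells=int(vals.size))


def surface_difference(a: DensitySurface, b: DensitySurface) -> ComparisonSurface:
    """Cellwise ``a - b``; positive values mark higher density in ``a``.

    The null value (no difference) is 0. NODATA in either operand
    propagates.
    """
    _check_grids(a, b)
    return ComparisonSurface(grid=a.grid, values=a.values - b.values, kind="difference")


def surface_ratio(a: DensitySurface, b: DensitySurface) -> ComparisonSurface:
    """Cellwise ``a / b``; the null value is 1.

    Cells where ``b`` is zero become NODATA rather than infinities, so
    the result stays representable in plain-text rasters.
    """
    _check_grids(a, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = a.values / b.values
    vals = np.where(b.values == 0.0, np.nan, vals)
    return ComparisonSurface(grid=a.grid, values=vals, kind="ratio")


def extreme_mask(surface: DensitySurface, n_sd: float = 2.0) -> ComparisonSurface:
    """1 where the cell strictly exceeds the surface's own mean + n_sd*sd, else 0."""
    stats = surface_stats(surface, n_sd=n_sd)
    vals = np.where(surface.values > stats.threshold, 1.0, 0.0)
    vals = np.where(np.isnan(surface.values), np.nan, vals)
    return ComparisonSurface(grid=surface.grid, values=vals, kind="mask", parent_stats=(stats,))


def indicator_difference(a: DensitySurface, b: DensitySurface, n_sd: float = 2.0) -> ComparisonSurface:
    """Three-valued map ``I(a extreme) - I(b extreme)``.

    Each surface is thresholded against its OWN mean + n_sd * sd. A cell
    is 1 when only ``a`` is extreme there, -1 when only ``b`` is, and 0
    when both or neither are.
    """
    _check_grids(a, b)
    ma = extreme_mask(a, n_sd=n_sd)
    mb = extreme_mask(b, n_sd=n_sd)
    return ComparisonSurface(
        grid=a.grid,
        values=ma.values - mb.values,
        kind="indicator_difference",
        parent_stats=(ma.parent_stats[0], mb.parent_stats[0]),
    )
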