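"""Terrain illumination geometry: slope, aspect and the solar incidence cosine.

Slope and aspect are derived from a DEM with Horn's 3x3 weighted
finite-difference kernel, the standard estimator for raster DEM derivatives.
Aspect follows the GIS convention: azimuth of the steepest *descent*
direction, degrees clockwise from north — the same convention as the solar
azimuth, so that the difference (azimuth - aspect) entering the incidence
formula is consistent. The cosine of the effective solar incidence angle at
each pixel is

    cos i = cos(theta) * cos(alpha) + sin(theta) * sin(alpha) * cos(phi - beta)

with solar zenith theta, slope alpha, solar azimuth phi and aspect beta.
A slope facing the sun (beta = phi) with alpha = theta is sun-normal
(cos i = 1); flat pixels reduce to cos i = cos(theta).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster import Georeference

__all__ = ["SolarGeometry", "TerrainGrids", "slope_aspect", "cos_incidence"]


@dataclass(frozen=True)
class SolarGeometry:
    """Solar position: zenith and azimuth in degrees (azimuth clockwise from N)."""

    zenith: float
    azimuth: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.zenith < 90.0:
            raise ValueError(f"solar zenith must be in [0, 90), got {self.zenith}")
        if not 0.0 <= self.azimuth < 360.0:
            raise ValueError(f"solar azimuth must be in [0, 360), got {self.azimuth}")


@dataclass
class TerrainGrids:
    """Slope/aspect (degrees) and solar incidence cosine grids from one DEM.

    ``aspect`` is NaN on flat cells (``flat_mask`` True there); ``valid`` is
    False on border cells and cells adjacent to nodata, where the 3x3 kernel
    is undefined. ``cos_i`` is filled by :func:`cos_incidence`.
    """

    slope: np.ndarray
    aspect: np.ndarray
    flat_mask: np.ndarray
    valid: np.ndarray
    cos_i: np.ndarray | None = None
    georef: Georeference = field(default_factory=Georeference)

    @property
    def shape(self) -> tuple[int, int]:
        return self.slope.shape


def slope_aspect(dem: np.ndarray, cell_size: float,
                 georef: Georeference | None = None) -> TerrainGrids:
    """Derive slope and aspect grids from a DEM (Horn 3x3 kernel).

    Parameters
    ----------
    dem : 2D array of elevations in meters; NaN marks nodata.
    cell_size : ground distance between cell centers, meters (> 0).

    Returns a :class:`TerrainGrids` with slope in [0, 90] degrees, aspect in
    [0, 360) degrees clockwise from north (NaN on flat cells), and the
    validity / flat masks. ``cos_i`` is left unfilled.
    """
    dem = np.asarray(dem, dtype=float)
    if cell_size <= 0:
        raise ValueError(f"cell_size must be positive, got {cell_size}")
    if dem.ndim != 2 or dem.shape[0] < 3 or dem.shape[1] < 3:
        raise ValueError(f"DEM must be at least 3x3, got shape {dem.shape}")

    finite = np.isfinite(dem)
    z = np.where(finite, dem, 0.0)

    # 3x3 neighborhoods; row 0 is the northern edge.
    nw, n_, ne = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    w_, e_ = z[1:-1, :-2], z[1:-1, 2:]
    sw, s_, se = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]

    # Horn weights: dz/dx positive eastward, dz/dy positive northward.
    dzdx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8.0 * cell_size)
    dzdy = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8.0 * cell_size)

    slope_core = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    flat_core = (dzdx == 0) & (dzdy == 0)
    # Aspect = azimuth of steepest descent = direction of -gradient.
    aspect_core = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    aspect_core[flat_core] = np.nan

    # Valid where the full 3x3 neighborhood is finite.
    fwin = finite
    ok = (
        fwin[:-2, :-2] & fwin[:-2, 1:-1] & fwin[:-2, 2:]
        & fwin[1:-1, :-2] & fwin[1:-1, 1:-1] & fwin[1:-1, 2:]
        & fwin[2:, :-2] & fwin[2:, 1:-1] & fwin[2:, 2:]
    )

    shape = dem.shape
    slope = np.full(shape, np.nan)
    aspect = np.full(shape, np.nan)
    flat = np.zeros(shape, dtype=bool)
    valid = np.zeros(shape, dtype=bool)
    slope[1:-1, 1:-1] = np.where(ok, slope_core, np.nan)
    aspect[1:-1, 1:-1] = np.where(ok, aspect_core, np.nan)
    flat[1:-1, 1:-1] = flat_core & ok
    valid[1:-1, 1:-1] = ok

    if georef is None:
        georef = Georeference(cell_size=cell_size)
    return TerrainGrids(slope, aspect, flat, valid, georef=georef)


def cos_incidence(terrain: TerrainGrids, solar: SolarGeometry) -> TerrainGrids:
    """Fill ``terrain.cos_i`` with the effective solar incidence cosine.

    Flat cells (undefined aspect) take the alpha -> 0 limit, cos i =
    cos(zenith). Invalid cells propagate as NaN. Returns ``terrain`` with
    ``cos_i`` populated (modified in place as well).
    """
    if terrain.slope.shape != terrain.aspect.shape:
        raise ValueError("slope and aspect grids have mismatched shapes")
    theta = np.radians(solar.zenith)
    phi = np.radians(solar.azimuth)
    alpha = np.radians(terrain.slope)
    beta = np.radians(terrain.aspect)

    with np.errstate(invalid="ignore"):
        cos_i = (np.cos(theta) * np.cos(alpha)
                 + np.sin(theta) * np.sin(alpha) * np.cos(phi - beta))
    cos_i = np.where(terrain.flat_mask, np.cos(theta), cos_i)
    cos_i = np.where(terrain.valid, cos_i, np.nan)
    terrain.cos_i = cos_i
    return terrain
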