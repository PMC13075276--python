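"""Topographic correction of multiband reflectance: SCS, SCS+C, Minnaert+SCS.

The sun-canopy-sensor (SCS) family normalizes each pixel's reflectance by
the ratio of flat-terrain to actual solar illumination:

    SCS:          rho_c = rho * cos(alpha) * cos(theta) / cos(i)
    SCS+C:        rho_c = rho * (cos(theta) * cos(alpha) + C) / (cos(i) + C)
    Minnaert+SCS: rho_c = rho * (cos(theta) / cos(i))**k * cos(alpha)

The per-band empirical parameters are estimated from the image itself:
C = B/A from the OLS fit rho = A * cos(i) + B (diffuse-irradiance
compensation), and the Minnaert exponent k from a log-linear regression of
illumination-adjusted reflectance on ln(cos i / cos theta) (non-Lambertian
scattering). All three corrections are the identity on flat terrain and are
linear in rho.

Numerical safeguards: pixels with cos i below ``COS_I_FLOOR`` are masked
out (correction factors explode in deep shadow); factors outside
``FACTOR_BOUNDS`` are counted per band as over-correction but still
applied; corrected reflectance is re-clipped to [0, 1] with the clipped
pixel count recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .raster import ReflectanceStack
from .terrain import SolarGeometry, TerrainGrids

__all__ = [
    "CorrectionParams", "BandFit", "DegenerateFitError",
    "scs_correct", "fit_c", "scs_c_correct", "fit_k", "minnaert_scs_correct",
    "fit_params", "correct", "METHODS",
]

#: cos i below this is treated as unusable shadow and masked out.
COS_I_FLOOR = 0.01
#: Correction factors outside this range are flagged as over-correction.
FACTOR_BOUNDS = (0.2, 5.0)
#: |A| below this (reflectance per cosine unit) is a degenerate SCS+C fit.
DEGENERATE_SLOPE_TOL = 1e-8

METHODS = ("scs", "scs+c", "minnaert+scs")


class DegenerateFitError(ValueError):
    """Raised when an empirical-parameter regression is degenerate."""


@dataclass(frozen=True)
class BandFit:
    """Per-band empirical parameter fit (C or k) with regression diagnostics."""

    band: str
    value: float  # C for SCS+C, k for Minnaert+SCS
    fit_r2: float
    fit_n: int
    A: float | None = None  # slope of rho on cos i (SCS+C only)
    B: float | None = None  # intercept (SCS+C only)


@dataclass
class CorrectionParams:
    """Empirical parameters of one correction method, one record per band."""

    method: str
    fits: dict[str, BandFit] = field(default_factory=dict)

    def value(self, band: str) -> float:
        return self.fits[band].value


def _check_registration(stack: ReflectanceStack, terrain: TerrainGrids) -> None:
    if stack.shape != terrain.shape:
        raise ValueError(
            f"stack shape {stack.shape} does not match terrain shape {terrain.shape}"
        )
    if terrain.cos_i is None:
        raise ValueError("terrain.cos_i is not populated; run cos_incidence first")


def _apply_factor(stack: ReflectanceStack, factor: np.ndarray,
                  usable: np.ndarray) -> ReflectanceStack:
    """Apply a per-pixel (or per-band) multiplicative factor; bookkeeping.

    ``factor`` has shape (n_bands, rows, cols) or (rows, cols). Returns a new
    stack with ``overcorrected`` and ``clipped`` per-band counts attached.
    """
    out = stack.copy()
    mask = stack.mask & usable
    if factor.ndim == 2:
        factor = np.broadcast_to(factor, stack.bands.shape)
    lo, hi = FACTOR_BOUNDS
    over = []
    clipped = []
    bands = np.where(mask, stack.bands * factor, np.nan)
    for b in range(bands.shape[0]):
        f = factor[b][mask]
        over.append(int(np.sum((f < lo) | (f > hi))))
        n_clip = int(np.sum((bands[b][mask] < 0) | (bands[b][mask] > 1)))
        clipped.append(n_clip)
    bands = np.clip(bands, 0.0, 1.0)
    bands[:, ~mask] = np.nan
    out.bands = bands
    out.mask = mask
    out.overcorrected = dict(zip(stack.band_names, over))
    out.clipped = dict(zip(stack.band_names, clipped))
    return out


def scs_correct(stack: ReflectanceStack, terrain: TerrainGrids,
                solar: SolarGeometry) -> ReflectanceStack:
    """SCS correction: rho_c = rho * cos(alpha) * cos(theta) / cos(i)."""
    _check_registration(stack, terrain)
    theta = np.radians(solar.zenith)
    cos_a = np.cos(np.radians(terrain.slope))
    usable = terrain.valid & (terrain.cos_i > COS_I_FLOOR)
    with np.errstate(invalid="ignore", divide="ignore"):
        factor = cos_a * np.cos(theta) / terrain.cos_i
    return _apply_factor(stack, factor, usable)


def scs_c_correct(stack: ReflectanceStack, terrain: TerrainGrids,
                  solar: SolarGeometry, params: CorrectionParams) -> ReflectanceStack:
    """SCS+C correction with per-band C from ``params``."""
    _check_registration(stack, terrain)
    theta = np.radians(solar.zenith)
    cos_a = np.cos(np.radians(terrain.slope))
    factors = np.empty_like(stack.bands)
    usable = terrain.valid & (terrain.cos_i > COS_I_FLOOR)
    for b, name in enumerate(stack.band_names):
        c = params.value(name)
        denom = terrain.cos_i + c
        with np.errstate(invalid="ignore", divide="ignore"):
            factors[b] = (np.cos(theta) * cos_a + c) / denom
        usable = usable & ~(denom <= 0)
    return _apply_factor(stack, factors, usable)


def minnaert_scs_correct(stack: ReflectanceStack, terrain: TerrainGrids,
                         solar: SolarGeometry,
                         params: CorrectionParams) -> ReflectanceStack:
    """Minnaert+SCS correction with per-band exponent k from ``params``."""
    _check_registration(stack, terrain)
    theta = np.radians(solar.zenith)
    cos_a = np.cos(np.radians(terrain.slope))
    usable = terrain.valid & (terrain.cos_i > COS_I_FLOOR)
    factors = np.empty_like(stack.bands)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.cos(theta) / terrain.cos_i
        for b, name in enumerate(stack.band_names):
            factors[b] = np.power(ratio, params.value(name)) * cos_a
    return _apply_factor(stack, factors, usable)


def fit_c(band: np.ndarray, cos_i: np.ndarray, mask: np.ndarray,
          band_name: str = "band") -> BandFit:
    """Estimate the SCS+C diffuse parameter C = B/A from rho = A*cos i + B.

    Ordinary least squares over valid pixels; raises
    :class:`DegenerateFitError` when the slope A is below tolerance or fewer
    than 3 valid pixels remain.
    """
    ok = mask & np.isfinite(band) & np.isfinite(cos_i)
    x, y = cos_i[ok], band[ok]
    if x.size < 3:
        raise DegenerateFitError(
            f"{band_name}: only {x.size} valid pixels for C fit (need >= 3)")
    if np.ptp(x) == 0:
        raise DegenerateFitError(f"{band_name}: cos i has zero variance")
    res = stats.linregress(x, y)
    if abs(res.slope) < DEGENERATE_SLOPE_TOL:
        raise DegenerateFitError(
            f"{band_name}: degenerate C fit, |A|={abs(res.slope):.2e} below "
            f"{DEGENERATE_SLOPE_TOL}")
    return BandFit(band=band_name, value=res.intercept / res.slope,
                   fit_r2=res.rvalue ** 2, fit_n=int(x.size),
                   A=res.slope, B=res.intercept)


def fit_k(band: np.ndarray, cos_i: np.ndarray, solar: SolarGeometry,
          mask: np.ndarray, band_name: str = "band",
          slope: np.ndarray | None = None,
          slope_adjusted: bool = True) -> BandFit:
    """Estimate the Minnaert exponent k by log-linear regression.

    With ``slope_adjusted`` (default) the response is ln(rho * cos alpha) —
    the exact log-linearisation of the Minnaert+SCS model, which makes the
    fit/correct round trip exact on noise-free forward scenes. With
    ``slope_adjusted=False`` the response is ln(rho), the approximate form
    that ignores the slope term. The regressor is ln(cos i / cos theta) in
    both cases; the OLS slope is k.
    """
    ok = (mask & np.isfinite(band) & np.isfinite(cos_i)
          & (band > 0) & (cos_i > 0))
    if slope_adjusted:
        if slope is None:
            raise ValueError("slope grid required when slope_adjusted=True")
        cos_a = np.cos(np.radians(slope))
        ok = ok & np.isfinite(cos_a) & (cos_a > 0)
    x_all = np.log(cos_i / np.cos(np.radians(solar.zenith)))
    if x_all[ok].size < 3:
        raise DegenerateFitError(
            f"{band_name}: fewer than 3 valid positive pixels for k fit")
    if np.ptp(x_all[ok]) == 0:
        raise DegenerateFitError(f"{band_name}: zero variance in ln(cos i/cos theta)")
    y = np.log(band[ok] * (np.cos(np.radians(slope[ok])) if slope_adjusted else 1.0))
    res = stats.linregress(x_all[ok], y)
    return BandFit(band=band_name, value=res.slope, fit_r2=res.rvalue ** 2,
                   fit_n=int(np.sum(ok)))


def fit_params(stack: ReflectanceStack, terrain: TerrainGrids,
               solar: SolarGeometry, method: str,
               mask: np.ndarray | None = None) -> CorrectionParams:
    """Fit per-band empirical parameters for ``method`` on valid pixels.

    ``mask`` restricts the fit (e.g. to vegetated pixels); defaults to the
    stack mask intersected with usable terrain. SCS needs no parameters and
    returns an empty record.
    """
    method = method.lower()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    params = CorrectionParams(method=method)
    if method == "scs":
        return params
    base = stack.mask & terrain.valid & (terrain.cos_i > COS_I_FLOOR)
    if mask is not None:
        base = base & mask
    for b, name in enumerate(stack.band_names):
        if method == "scs+c":
            params.fits[name] = fit_c(stack.bands[b], terrain.cos_i, base, name)
        else:
            params.fits[name] = fit_k(stack.bands[b], terrain.cos_i, solar,
                                      base, name, slope=terrain.slope)
    return params


def correct(stack: ReflectanceStack, terrain: TerrainGrids, solar: SolarGeometry,
            method: str, params: CorrectionParams | None = None,
            fit_mask: np.ndarray | None = None,
            ) -> tuple[ReflectanceStack, CorrectionParams]:
    """Fit parameters (unless given) and apply the named correction."""
    method = method.lower()
    if params is None:
        params = fit_params(stack, terrain, solar, method, mask=fit_mask)
    if method == "scs":
        return scs_correct(stack, terrain, solar), params
    if method == "scs+c":
        return scs_c_correct(stack, terrain, solar, params), params
    if method == "minnaert+scs":
        return minnaert_scs_correct(stack, terrain, solar, params), params
    raise ValueError(f"unknown method {method!r}")
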