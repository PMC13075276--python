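"""Canopy feature extraction: band means, 16 vegetation indices, GLCM texture.

Each canopy sample yields a 61-dimensional feature vector: the 5 band mean
reflectances, 16 vegetation indices computed from those means, and 40
texture values (8 gray-level co-occurrence metrics per band, averaged over
canopy pixels). Features are min-max normalized to [-1, 1].

GLCM texture is computed per pixel on a 3x3 sliding window after 64-level
quantization over the band's global valid range. For each of the four
offsets (0, 45, 90, 135 degrees) at distance 1, a symmetric normalized
co-occurrence matrix is accumulated from the pixel pairs inside the window
(windows truncate at raster edges), eight Haralick-style metrics are
evaluated, and the four directions are averaged. Zero-variance windows take
Correlation = 0 by convention (the 0/0 case); windows with fewer than two
valid pairs in a direction are flagged missing (NaN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .raster import BAND_NAMES, Georeference, ReflectanceStack

__all__ = [
    "CanopySample", "FeatureTable", "VI_NAMES", "TEXTURE_METRICS",
    "FEATURE_COLUMNS", "vegetation_indices", "glcm_texture",
    "canopy_mean_reflectance", "canopy_texture", "assemble_features",
    "normalize_features", "sample_pixel_mask",
]

VI_NAMES = ("SR", "DVI", "NDVI", "NDRE", "SAVI", "EVI", "OSAVI", "TriVI",
            "GNDVI", "GBNDVI", "VARI", "RGBVI", "GLI", "NLI", "MTVI2", "MSR")

TEXTURE_METRICS = ("Mean", "Variance", "Homogeneity", "Contrast",
                   "Dissimilarity", "Entropy", "SecondMoment", "Correlation")

#: Fixed 61-column ordering: 5 bands, 16 VIs, then 8 metrics per band.
FEATURE_COLUMNS = (
    list(BAND_NAMES)
    + list(VI_NAMES)
    + [f"{metric}_{band}" for band in BAND_NAMES for metric in TEXTURE_METRICS]
)

#: Offsets (drow, dcol) for directions 0, 45, 90, 135 degrees at distance 1.
DIRECTION_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

#: Default radius (m) used to buffer point samples into canopy regions.
DEFAULT_POINT_BUFFER = 0.5


@dataclass
class CanopySample:
    """One sampled plant: id, canopy geometry (map units), optional LAI."""

    sample_id: str
    geometry: BaseGeometry
    reference_lai: float | None = None


@dataclass
class FeatureTable:
    """Per-sample feature matrix plus reference LAI and normalization record.

    ``data`` is indexed by sample_id with exactly the 61 ``FEATURE_COLUMNS``
    plus ``reference_lai``; ``norm_record`` maps feature -> (min, max) once
    :func:`normalize_features` has been applied.
    """

    data: pd.DataFrame
    norm_record: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in FEATURE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing[:5]}...")
        extra = [c for c in self.data.columns
                 if c not in FEATURE_COLUMNS and c != "reference_lai"]
        if extra:
            raise ValueError(f"unexpected feature columns: {extra}")

    @property
    def features(self) -> pd.DataFrame:
        return self.data[list(FEATURE_COLUMNS)]

    @property
    def lai(self) -> pd.Series:
        return self.data["reference_lai"]

    def modelling_rows(self) -> "FeatureTable":
        """Rows with a reference LAI and no missing feature."""
        ok = self.data["reference_lai"].notna() & self.features.notna().all(axis=1)
        return FeatureTable(self.data.loc[ok].copy(), dict(self.norm_record))


# ---------------------------------------------------------------------------
# Vegetation indices
# ---------------------------------------------------------------------------

def vegetation_indices(band_means: dict[str, float]) -> dict[str, float]:
    """Evaluate the 16 vegetation indices from per-band mean reflectance.

    ``band_means`` must contain Blue, Green, Red, RedEdge, NIR. An index
    whose denominator is zero (or whose formula is otherwise undefined,
    e.g. a negative square-root argument) is returned as NaN rather than
    silently zero.
    """
    b = band_means["Blue"]
    g = band_means["Green"]
    r = band_means["Red"]
    re = band_means["RedEdge"]
    nir = band_means["NIR"]

    def ratio(num, den):
        return num / den if den != 0 else float("nan")

    out = {
        "SR": ratio(nir, r),
        "DVI": nir - r,
        "NDVI": ratio(nir - r, nir + r),
        "NDRE": ratio(nir - re, nir + re),
        "SAVI": ratio(1.5 * (nir - r), nir + r + 0.5),
        "EVI": ratio(2.5 * (nir - r), nir + 6.0 * r - 7.5 * b + 1.0),
        "OSAVI": ratio(nir - r, nir + r + 0.16),
        "TriVI": 0.5 * (120.0 * (nir - g) - 200.0 * (r - g)),
        "GNDVI": ratio(nir - g, nir + g),
        "GBNDVI": ratio(nir - (g + b), nir + (g + b)),
        "VARI": ratio(g - r, g + r - b),
        "RGBVI": ratio(g * g - b * r, g * g + b * r),
        "GLI": ratio(2.0 * g - r - b, 2.0 * g + r + b),
        "NLI": ratio(nir * nir - r, nir * nir + r),
    }
    if r >= 0:
        arg = (2.0 * nir + 1.0) ** 2 - (6.0 * nir - 5.0 * np.sqrt(r)) - 0.5
        out["MTVI2"] = (1.5 * (1.2 * (nir - g) - 2.5 * (r - g)) / np.sqrt(arg)
                        if arg > 0 else float("nan"))
    else:
        out["MTVI2"] = float("nan")
    if r != 0:
        sr = nir / r
        out["MSR"] = ((sr - 1.0) / np.sqrt(sr + 1.0) if sr + 1.0 > 0
                      else float("nan"))
    else:
        out["MSR"] = float("nan")
    return out


# ---------------------------------------------------------------------------
# GLCM texture
# ---------------------------------------------------------------------------

def quantize(band: np.ndarray, levels: int = 64,
             mask: np.ndarray | None = None) -> np.ndarray:
    """Quantize a band to integer gray levels over its global valid range.

    Returns an int array with -1 on invalid pixels. Raises on a constant
    band (zero dynamic range makes quantization undefined).
    """
    band = np.asarray(band, dtype=float)
    valid = np.isfinite(band)
    if mask is not None:
        valid = valid & np.asarray(mask, dtype=bool)
    vals = band[valid]
    if vals.size == 0:
        raise ValueError("no valid pixels to quantize")
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        raise ValueError("constant band: zero dynamic range, cannot quantize")
    scaled = np.floor((np.where(valid, band, lo) - lo) / (hi - lo) * levels)
    q = np.clip(scaled, 0, levels - 1).astype(int)
    q[~valid] = -1
    return q


def _window_pairs(offset: tuple[int, int]) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Relative (first, second) pixel positions of all distance-1 pairs at
    ``offset`` that fit inside a 3x3 window centered at (0, 0)."""
    dr, dc = offset
    pairs = []
    for a in (-1, 0, 1):
        for b in (-1, 0, 1):
            if -1 <= a + dr <= 1 and -1 <= b + dc <= 1:
                pairs.append(((a, b), (a + dr, b + dc)))
    return pairs


def _direction_metrics(q: np.ndarray, offset: tuple[int, int],
                       levels: int) -> dict[str, np.ndarray]:
    """Per-pixel GLCM metrics for one direction (vectorized over windows)."""
    h, w = q.shape
    pad = 2
    qp = np.full((h + 2 * pad, w + 2 * pad), -1, dtype=int)
    qp[pad:-pad, pad:-pad] = q

    def shifted(dr, dc):
        return qp[pad + dr: pad + dr + h, pad + dc: pad + dc + w]

    firsts, seconds = [], []
    for (a, b), (a2, b2) in _window_pairs(offset):
        i, j = shifted(a, b), shifted(a2, b2)
        firsts += [i, j]   # symmetric matrix: count both orders
        seconds += [j, i]
    I = np.stack(firsts).astype(float)    # (2P, h, w)
    J = np.stack(seconds).astype(float)
    V = (I >= 0) & (J >= 0)

    m = V.sum(axis=0).astype(float)        # ordered entries per window
    enough = m >= 4                        # at least 2 valid pairs
    with np.errstate(invalid="ignore", divide="ignore"):
        wgt = np.where(V, 1.0, 0.0) / np.where(m > 0, m, np.nan)

        mean = np.nansum(wgt * I, axis=0)
        var = np.nansum(wgt * (I - mean) ** 2, axis=0)
        contrast = np.nansum(wgt * (I - J) ** 2, axis=0)
        dissim = np.nansum(wgt * np.abs(I - J), axis=0)
        homog = np.nansum(wgt / (1.0 + (I - J) ** 2), axis=0)
        cov = np.nansum(wgt * (I - mean) * (J - mean), axis=0)
        corr = np.where(var > 0, cov / np.where(var > 0, var, 1.0), 0.0)

        # Multiplicity of each ordered entry within its window: invalid
        # entries get unique sentinel codes so they never match anything.
        codes = np.where(V, I.astype(int) * levels + J.astype(int),
                         levels * levels + np.arange(I.shape[0])[:, None, None])
        counts = (codes[:, None, :, :] == codes[None, :, :, :]).sum(axis=1)
        asm = np.nansum(np.where(V, counts, 0.0), axis=0) / np.where(
            m > 0, m, np.nan) ** 2
        entropy = -np.nansum(
            np.where(V, np.log(counts / np.where(m > 0, m, np.nan)), 0.0),
            axis=0) / np.where(m > 0, m, np.nan)

    out = {"Mean": mean, "Variance": var, "Homogeneity": homog,
           "Contrast": contrast, "Dissimilarity": dissim, "Entropy": entropy,
           "SecondMoment": asm, "Correlation": corr}
    for k in out:
        out[k] = np.where(enough, out[k], np.nan)
    return out


def glcm_texture(band: np.ndarray, window: int = 3, levels: int = 64,
                 mask: np.ndarray | None = None,
                 directions: tuple[int, ...] = (0, 45, 90, 135),
                 ) -> dict[str, np.ndarray]:
    """Per-pixel GLCM texture metrics, averaged over the given directions.

    Returns a dict of eight metric grids co-registered with ``band``.
    Only ``window=3`` is supported (the window the pipeline uses); the
    parameter is validated to keep the contract explicit.
    """
    if window != 3 or window % 2 == 0:
        raise ValueError("only the odd 3x3 window is supported")
    q = quantize(band, levels=levels, mask=mask)
    per_dir = [_direction_metrics(q, DIRECTION_OFFSETS[d], levels)
               for d in directions]
    return {metric: np.mean([d[metric] for d in per_dir], axis=0)
            for metric in TEXTURE_METRICS}


def stack_texture(stack: ReflectanceStack, levels: int = 64,
                  ) -> dict[str, dict[str, np.ndarray]]:
    """GLCM metrics for every band of a stack: {band: {metric: grid}}."""
    return {name: glcm_texture(stack.bands[i], levels=levels, mask=stack.mask)
            for i, name in enumerate(stack.band_names)}


# ---------------------------------------------------------------------------
# Canopy aggregation
# ---------------------------------------------------------------------------

def sample_pixel_mask(sample: CanopySample, georef: Georeference,
                      shape: tuple[int, int],
                      point_buffer: float = DEFAULT_POINT_BUFFER) -> np.ndarray:
    """Boolean grid of pixels whose centers fall inside the canopy geometry.

    Point geometries are buffered to ``point_buffer`` meters; polygons are
    used as-is (pixel-center membership, no partial-pixel weighting).
    """
    geom = sample.geometry
    if isinstance(geom, Point):
        geom = geom.buffer(point_buffer)
    x, y = georef.pixel_centers(shape)
    return shapely.contains_xy(geom, x, y)


def canopy_mean_reflectance(stack: ReflectanceStack, sample: CanopySample,
                            point_buffer: float = DEFAULT_POINT_BUFFER,
                            ) -> dict[str, float]:
    """Per-band mean reflectance over the sample's valid canopy pixels."""
    sel = sample_pixel_mask(sample, stack.georef, stack.shape, point_buffer)
    sel = sel & stack.mask
    if not sel.any():
        raise ValueError(f"sample {sample.sample_id}: no valid pixels in canopy")
    return {name: float(np.nanmean(stack.bands[b][sel]))
            for b, name in enumerate(stack.band_names)}


def canopy_texture(texture: dict[str, dict[str, np.ndarray]],
                   sample: CanopySample, georef: Georeference,
                   shape: tuple[int, int],
                   point_buffer: float = DEFAULT_POINT_BUFFER,
                   ) -> dict[str, float]:
    """Mean of each per-pixel texture metric over canopy pixels, per band."""
    sel = sample_pixel_mask(sample, georef, shape, point_buffer)
    if not sel.any():
        raise ValueError(f"sample {sample.sample_id}: no pixels in canopy")
    out = {}
    for band, metrics in texture.items():
        for metric, grid in metrics.items():
            vals = grid[sel]
            vals = vals[np.isfinite(vals)]
            out[f"{metric}_{band}"] = float(vals.mean()) if vals.size else float("nan")
    return out


def assemble_features(samples: list[CanopySample], stack: ReflectanceStack,
                      texture: dict[str, dict[str, np.ndarray]] | None = None,
                      point_buffer: float = DEFAULT_POINT_BUFFER,
                      ) -> FeatureTable:
    """Build the 61-column feature table for a list of canopy samples.

    Texture grids are computed from ``stack`` when not supplied. Rows with
    any missing feature are kept in the table (NaN) but excluded by
    :meth:`FeatureTable.modelling_rows`.
    """
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicated sample_id(s): {dupes}")
    if texture is None:
        texture = stack_texture(stack)
    rows = []
    for s in samples:
        means = canopy_mean_reflectance(stack, s, point_buffer)
        row = dict(means)
        row.update(vegetation_indices(means))
        row.update(canopy_texture(texture, s, stack.georef, stack.shape,
                                  point_buffer))
        row["reference_lai"] = (float(s.reference_lai)
                                if s.reference_lai is not None else np.nan)
        rows.append(row)
    data = pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"))
    data = data[list(FEATURE_COLUMNS) + ["reference_lai"]]
    return FeatureTable(data)


def normalize_features(table: FeatureTable,
                       fit_rows: np.ndarray | list | None = None) -> FeatureTable:
    """Min-max normalize every feature to [-1, 1].

    The transform x' = 2 * (x - min) / (max - min) - 1 uses min/max from
    ``fit_rows`` (all rows by default); rows outside ``fit_rows`` may fall
    outside [-1, 1] and are deliberately not clipped. The (min, max) record
    is stored so the transform is invertible.
    """
    data = table.data.copy()
    fit = data if fit_rows is None else data.loc[fit_rows]
    record = {}
    for col in FEATURE_COLUMNS:
        lo, hi = fit[col].min(), fit[col].max()
        if not np.isfinite(lo) or not np.isfinite(hi) or hi == lo:
            raise ValueError(f"feature {col!r} is constant/empty over fit rows")
        data[col] = 2.0 * (data[col] - lo) / (hi - lo) - 1.0
        record[col] = (float(lo), float(hi))
    return FeatureTable(data, record)
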