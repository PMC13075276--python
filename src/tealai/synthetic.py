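"""Synthetic terrain scenes and canopy sample sets for end-to-end testing.

The generator emulates the statistical structure the analysis assumes — a
hilly low-mountain DEM (elevations 58-186 m), five-band reflectance at
realistic magnitudes, 90 canopy samples with a right-skewed LAI
distribution (range ~1.0-9.5, mean ~3.8, CV ~0.56) — and pushes the true
reflectance through a configurable illumination forward model (the exact
algebraic inverse of the matching topographic correction) plus seeded
Gaussian noise. Because the true reflectance, the forward parameters and
every sample's LAI are recorded, every pipeline stage can be validated by
parameter recovery rather than against withheld field data.

Spatial scales are compressed relative to a real acquisition: cells default
to 4 m (not centimetres) and canopy footprints are enlarged so each spans
enough pixels for texture statistics. All outputs are deterministic given
(config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import Point

from .features import CanopySample
from .ground_truth import FieldRecord, slw_lai
from .raster import BAND_NAMES, Georeference, ReflectanceStack
from .terrain import SolarGeometry, TerrainGrids, cos_incidence, slope_aspect

__all__ = ["SceneConfig", "SyntheticScene", "make_dem", "make_scene",
           "make_samples"]

FORWARD_MODELS = ("lambertian-scs", "scs+c", "minnaert")

#: Hard sanity bounds on forward illumination factors.
FACTOR_SANITY = (0.1, 10.0)


@dataclass(frozen=True)
class SceneConfig:
    """Generator settings; defaults are the emulated study conditions."""

    shape: tuple[int, int] = (128, 128)
    cell_size: float = 4.0                      # m
    elevation_range: tuple[float, float] = (58.0, 186.0)  # m
    solar: SolarGeometry = field(default_factory=lambda: SolarGeometry(23.3, 157.8))
    #: per-band scene base reflectance (canopy-free background level).
    band_base: dict[str, float] = field(default_factory=lambda: {
        "Blue": 0.06373, "Green": 0.10965, "Red": 0.05311,
        "RedEdge": 0.20555, "NIR": 0.25790})
    forward_model: str = "scs+c"
    #: true diffuse parameter per band (scs+c); larger in the visible where
    #: the diffuse-sky fraction is higher.
    true_c: dict[str, float] = field(default_factory=lambda: {
        "Blue": 1.0, "Green": 0.7, "Red": 0.9, "RedEdge": 0.5, "NIR": 0.35})
    #: true Minnaert exponent per band (minnaert model).
    true_k: dict[str, float] = field(default_factory=lambda: {
        "Blue": 0.55, "Green": 0.6, "Red": 0.6, "RedEdge": 0.7, "NIR": 0.75})
    noise_sd: float = 0.003                     # reflectance units
    n_samples: int = 90
    lai_mean: float = 3.81
    lai_cv: float = 0.5572
    lai_range: tuple[float, float] = (1.04, 9.45)
    canopy_radius: tuple[float, float] = (8.0, 12.0)  # m
    #: strength of the saturating LAI -> band-reflectance coupling.
    vi_coupling: float = 1.0
    #: strength of the LAI -> within-canopy speckle (gap pattern) coupling.
    texture_coupling: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.forward_model not in FORWARD_MODELS:
            raise ValueError(f"forward_model must be one of {FORWARD_MODELS}")
        if self.n_samples < 5:
            raise ValueError("n_samples must be >= 5")
        if self.elevation_range[1] <= self.elevation_range[0]:
            raise ValueError("elevation range must be increasing")
        if min(self.shape) < 8:
            raise ValueError("degenerate grid size")

    def texture_dominant(self) -> "SceneConfig":
        """Variant where canopy structure (texture) drives the signal and the
        spectral coupling is weak — the structure-dominance regime."""
        return replace(self, vi_coupling=0.15, texture_coupling=2.0)


@dataclass
class SyntheticScene:
    """A generated scene with full ground truth."""

    config: SceneConfig
    dem: np.ndarray
    terrain: TerrainGrids
    observed: ReflectanceStack
    true: ReflectanceStack
    samples: list[CanopySample]
    field_records: list[FieldRecord]
    true_lai: dict[str, float]
    true_params: dict[str, float]   # per-band c or k (empty for pure SCS)


def make_dem(config: SceneConfig, seed: int | None = None) -> np.ndarray:
    """Seeded random hilly surface rescaled so min/max equal the configured
    elevation range exactly.

    The surface is a superposition of conical hills (upper envelope of
    cones dropped from random peaks), giving a dissected hill landscape
    whose slope magnitude is spatially uniform while aspect sweeps the full
    compass. A uniform gradient keeps the empirical correction-parameter
    regressions (C = B/A and the Minnaert log fit) statistically consistent
    with the forward model; on variable-gradient terrain those estimators
    carry a known geometric bias (see the methods note).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows, cols = config.shape
    y, x = np.mgrid[0:rows, 0:cols].astype(float)
    n_peaks = 8
    px = rng.uniform(0, cols - 1, n_peaks)
    py = rng.uniform(0, rows - 1, n_peaks)
    heights = rng.uniform(0.55, 1.0, n_peaks) * max(rows, cols) * 0.45
    z = np.full(config.shape, -np.inf)
    for cx, cy, h in zip(px, py, heights):
        z = np.maximum(z, h - np.hypot(x - cx, y - cy))
    lo, hi = config.elevation_range
    z = (z - z.min()) / (z.max() - z.min()) * (hi - lo) + lo
    return z


def _variation_field(rng, shape, sd: float) -> np.ndarray:
    """Zero-mean fine-grained multiplicative variation field.

    Pixel-independent variation is deliberately uncorrelated with terrain,
    so it perturbs the empirical parameter regressions without biasing
    them (a low-frequency field would alias onto cos i in any single
    realization)."""
    return rng.normal(0.0, sd, size=shape)


def _draw_lai(rng, config: SceneConfig, n: int) -> np.ndarray:
    """Right-skewed LAI: truncated log-normal hitting the target mean/CV."""
    sigma2 = math.log(1.0 + config.lai_cv ** 2)
    mu = math.log(config.lai_mean) - sigma2 / 2.0
    lo, hi = config.lai_range
    out = []
    while len(out) < n:
        draw = rng.lognormal(mu, math.sqrt(sigma2), size=4 * n)
        out.extend(draw[(draw >= lo) & (draw <= hi)].tolist())
    return np.asarray(out[:n])


def _place_samples(rng, config: SceneConfig, dem: np.ndarray,
                   radius_px: float) -> list[tuple[int, int]]:
    """Sample locations stratified across elevation and balanced across
    illumination.

    Emulates a balanced stratified field design: the elevation range is
    split into strata and each stratum contributes a matched pair — one
    plant on a weakly illuminated aspect (low cos i), one on a strongly
    illuminated aspect — subject to a non-overlap spacing constraint.
    Balancing aspect within strata keeps the sample set representative of
    the full illumination range without tilting the scene-wide
    reflectance-vs-cos i regressions.
    """
    from .terrain import cos_incidence as _cosinc, slope_aspect as _sa

    rows, cols = config.shape
    margin = int(math.ceil(radius_px)) + 2
    grids = _sa(dem, config.cell_size)
    _cosinc(grids, config.solar)
    rr, cc = np.mgrid[margin:rows - margin, margin:cols - margin]
    rr, cc = rr.ravel(), cc.ravel()
    cosi = grids.cos_i[rr, cc]
    ok = np.isfinite(cosi)
    rr, cc, cosi = rr[ok], cc[ok], cosi[ok]
    elev = dem[rr, cc]

    n_bins = (config.n_samples + 1) // 2
    bins = np.array_split(np.argsort(elev), n_bins)
    min_d2 = (2.0 * radius_px + 1.0) ** 2
    chosen: list[tuple[int, int]] = []

    def pick(candidates) -> bool:
        for idx in candidates:
            r, c = int(rr[idx]), int(cc[idx])
            if all((r - r0) ** 2 + (c - c0) ** 2 >= min_d2 for r0, c0 in chosen):
                chosen.append((r, c))
                return True
        return False

    for b in rng.permutation(len(bins)):
        members = bins[b][np.argsort(cosi[bins[b]])]
        n = len(members)
        shaded = rng.permutation(members[: max(1, n // 3)])
        sunlit = rng.permutation(members[-max(1, n // 3):])
        pick(shaded)
        if len(chosen) < config.n_samples:
            pick(sunlit)
        if len(chosen) >= config.n_samples:
            break
    if len(chosen) < config.n_samples:
        raise ValueError(
            f"could only place {len(chosen)}/{config.n_samples} samples; "
            "grid too small for the canopy radius")
    return chosen[: config.n_samples]


def make_samples(config: SceneConfig, dem: np.ndarray,
                 true_stack: ReflectanceStack, seed: int | None = None,
                 ) -> tuple[list[CanopySample], list[FieldRecord]]:
    """Place canopy samples, draw their LAI, and paint the LAI signal into
    the true reflectance stack (modified in place).

    Spectral channel: a saturating map f = 1 - exp(-0.45 * LAI) raises NIR
    and red-edge reflectance and darkens the visible bands within each
    canopy, so vegetation indices increase with LAI and saturate at high
    LAI. Texture channel: within-canopy multiplicative speckle whose
    standard deviation grows with LAI (denser canopies cast more
    self-shadow), shared across bands so it perturbs texture much more than
    band ratios. Field records are back-solved so the specific-leaf-weight
    formula reproduces each drawn LAI exactly.
    """
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 1_000_003)
    georef = true_stack.georef
    radius_px = max(config.canopy_radius) / config.cell_size
    centers = _place_samples(rng, config, dem, radius_px)
    # Matched pairs: consecutive centers are the shaded/sunlit members of an
    # elevation stratum; give them similar canopy density (adjacent order
    # statistics of the drawn LAI) and the same footprint, so illumination
    # and canopy structure are crossed, not confounded.
    n = config.n_samples
    n_pairs = (n + 1) // 2
    lai_sorted = np.sort(_draw_lai(rng, config, n))
    chunks = [lai_sorted[2 * i: 2 * i + 2] for i in range(n_pairs)]
    full = rng.permutation(n_pairs - 1 if n % 2 else n_pairs)
    slots = list(full) + ([n_pairs - 1] if n % 2 else [])
    lai = np.empty(n)
    for chunk, pair in zip(chunks, slots):
        vals = chunk[rng.permutation(len(chunk))]
        for j, v in enumerate(vals):
            lai[min(2 * pair + j, n - 1)] = v
    radii = np.repeat(rng.uniform(*config.canopy_radius, size=n_pairs), 2)[:n]

    rows, cols = config.shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    band_idx = {n: i for i, n in enumerate(true_stack.band_names)}
    #: per-band spectral response gain to the saturating LAI map.
    gain = {"Blue": -0.35, "Green": -0.15, "Red": -0.55,
            "RedEdge": 0.25, "NIR": 0.45}

    samples, records = [], []
    for i, ((r, c), L) in enumerate(zip(centers, lai)):
        radius_m = float(radii[i])
        rpx = radius_m / config.cell_size
        disk = (yy - r) ** 2 + (xx - c) ** 2 <= rpx ** 2
        f = 1.0 - math.exp(-0.45 * L)
        speckle_sd = config.texture_coupling * (0.02 + 0.12 * L / config.lai_range[1])
        speckle = 1.0 + rng.normal(0.0, speckle_sd, size=int(disk.sum()))
        speckle = np.clip(speckle, 0.2, 1.8)
        for name, g in gain.items():
            b = band_idx[name]
            level = true_stack.bands[b][disk]
            level = level * (1.0 + config.vi_coupling * g * f)
            true_stack.bands[b][disk] = np.clip(level * speckle, 0.001, 1.0)

        x, y = (georef.x0 + (c + 0.5) * georef.cell_size,
                georef.y0 - (r + 0.5) * georef.cell_size)
        sid = f"S{i + 1:03d}"
        samples.append(CanopySample(sid, Point(x, y).buffer(radius_m)))
        # Back-solve a plausible field record reproducing this LAI exactly.
        d1 = 2.0 * radius_m
        d2 = 2.0 * radius_m * rng.uniform(0.85, 1.0)
        area = math.pi * (d1 / 2.0) * (d2 / 2.0)
        w1 = rng.uniform(0.8, 1.2)
        s_area = rng.uniform(0.020, 0.030)
        m = int(rng.integers(30, 80))
        w2 = float(L) * area * w1 / (s_area * m)
        records.append(FieldRecord(sid, w1=w1, w2=w2, s=s_area, m=m,
                                   d1=d1, d2=d2))
    return samples, records


def _forward_factor(config: SceneConfig, terrain: TerrainGrids,
                    band: str) -> np.ndarray:
    """Illumination distortion factor: observed = true * factor."""
    theta = math.radians(config.solar.zenith)
    cos_a = np.cos(np.radians(terrain.slope))
    cos_i = terrain.cos_i
    if config.forward_model == "lambertian-scs":
        return cos_i / (cos_a * math.cos(theta))
    if config.forward_model == "scs+c":
        c = config.true_c[band]
        return (cos_i + c) / (math.cos(theta) * cos_a + c)
    k = config.true_k[band]
    return np.power(cos_i / math.cos(theta), k) / cos_a


def make_scene(config: SceneConfig | None = None,
               seed: int | None = None) -> SyntheticScene:
    """Generate a full synthetic scene with ground truth.

    Returns observed reflectance (forward-distorted + noise), the true
    reflectance, terrain grids, canopy samples with back-solved field
    records, per-sample true LAI, and the forward parameters.
    """
    config = config or SceneConfig()
    base_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(base_seed)

    dem = make_dem(config, seed=base_seed)
    georef = Georeference(x0=0.0, y0=config.shape[0] * config.cell_size,
                          cell_size=config.cell_size)
    terrain = slope_aspect(dem, config.cell_size, georef=georef)
    cos_incidence(terrain, config.solar)

    rows, cols = config.shape
    bands = np.empty((len(BAND_NAMES), rows, cols))
    for b, name in enumerate(BAND_NAMES):
        bands[b] = config.band_base[name] * (
            1.0 + _variation_field(rng, config.shape, 0.05))
    true_stack = ReflectanceStack(bands, BAND_NAMES,
                                  np.ones((rows, cols), dtype=bool), georef)

    samples, records = make_samples(config, dem, true_stack, seed=base_seed)
    true_lai = {s.sample_id: slw_lai(rec)
                for s, rec in zip(samples, records)}
    for s, rec in zip(samples, records):
        s.reference_lai = true_lai[s.sample_id]

    observed = true_stack.copy()
    lo, hi = FACTOR_SANITY
    for b, name in enumerate(BAND_NAMES):
        factor = _forward_factor(config, terrain, name)
        finite = factor[np.isfinite(factor)]
        if finite.size and (finite.min() < lo or finite.max() > hi):
            raise ValueError(
                f"forward factors outside sanity bounds {FACTOR_SANITY}: "
                f"[{finite.min():.3f}, {finite.max():.3f}] for band {name}")
        observed.bands[b] = true_stack.bands[b] * factor
        if config.noise_sd > 0:
            observed.bands[b] = observed.bands[b] + rng.normal(
                0.0, config.noise_sd, size=(rows, cols))
        observed.bands[b] = np.clip(observed.bands[b], 0.0, 1.0)
    observed.mask = observed.mask & terrain.valid & np.isfinite(terrain.cos_i)
    observed.bands[:, ~observed.mask] = np.nan

    if config.forward_model == "scs+c":
        true_params = dict(config.true_c)
    elif config.forward_model == "minnaert":
        true_params = dict(config.true_k)
    else:
        true_params = {}
    return SyntheticScene(config=config, dem=dem, terrain=terrain,
                          observed=observed, true=true_stack, samples=samples,
                          field_records=records, true_lai=true_lai,
                          true_params=true_params)
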