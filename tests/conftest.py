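import numpy as np
import pytest

from tealai.raster import BAND_NAMES, Georeference, ReflectanceStack
from tealai.terrain import SolarGeometry, cos_incidence, slope_aspect

#: Solar geometry of the emulated acquisition (noon, early April).
SOLAR = SolarGeometry(23.3, 157.8)


@pytest.fixture(scope="session")
def solar() -> SolarGeometry:
    return SOLAR


def cone_dem(n: int = 96, slope_deg: float = 20.0, cell: float = 1.0) -> np.ndarray:
    """Inverted cone: constant slope magnitude, aspect sweeping 0-360."""
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    r = np.hypot(yy - n / 2, xx - n / 2)
    return -r * cell * np.tan(np.radians(slope_deg))


@pytest.fixture(scope="session")
def cone_terrain(solar):
    """Terrain grids on a constant-slope cone with cos_i populated."""
    grids = slope_aspect(cone_dem(), 1.0)
    return cos_incidence(grids, solar)


def pyramid_dem(n: int = 64, slope_deg: float = 20.0) -> np.ndarray:
    """Square pyramid: four planar faces of exactly constant slope (aspect
    N/E/S/W); ridge and apex cells are the only non-planar ones."""
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    return -np.tan(np.radians(slope_deg)) * np.maximum(
        np.abs(xx - n / 2), np.abs(yy - n / 2))


def uniform_stack(shape=(96, 96), levels=None, georef=None) -> ReflectanceStack:
    """Spatially uniform five-band stack at realistic reflectance levels."""
    if levels is None:
        levels = {"Blue": 0.06373, "Green": 0.10965, "Red": 0.05311,
                  "RedEdge": 0.20555, "NIR": 0.25790}
    bands = np.stack([np.full(shape, levels[n]) for n in BAND_NAMES])
    return ReflectanceStack(bands, BAND_NAMES,
                            np.ones(shape, dtype=bool),
                            georef or Georeference(y0=shape[0] * 1.0))
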