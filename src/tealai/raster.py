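"""Raster containers and TIFF I/O.

Grids are row-major float arrays with row 0 at the northern edge, columns
increasing eastward. Georeferencing is a north-up affine: pixel (row, col)
has its center at ``(x0 + (col + 0.5) * cell, y0 - (row + 0.5) * cell)``.

Files are written as multiband TIFF with GeoTIFF ModelPixelScale /
ModelTiepoint tags and a JSON ImageDescription carrying band names, the
nodata value and the georeference, so round trips are lossless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

NODATA = -9999.0

#: Canonical band order of the five-band multispectral sensor.
BAND_NAMES = ("Blue", "Green", "Red", "RedEdge", "NIR")


@dataclass(frozen=True)
class Georeference:
    """North-up affine georeference: origin = top-left corner, square cells."""

    x0: float = 0.0
    y0: float = 0.0
    cell_size: float = 1.0

    def pixel_centers(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) coordinate grids of pixel centers for ``shape``."""
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
        x = self.x0 + (cols + 0.5) * self.cell_size
        y = self.y0 - (rows + 0.5) * self.cell_size
        return x, y

    def world_to_pixel(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map world coordinates to fractional (row, col) indices."""
        col = (np.asarray(x) - self.x0) / self.cell_size - 0.5
        row = (self.y0 - np.asarray(y)) / self.cell_size - 0.5
        return row, col


@dataclass
class ReflectanceStack:
    """Co-registered multiband surface-reflectance grids with a validity mask.

    ``bands`` has shape (n_bands, rows, cols); reflectance is unitless in
    [0, 1] on valid pixels. ``mask`` is True where pixels are valid.
    """

    bands: np.ndarray
    band_names: tuple[str, ...] = BAND_NAMES
    mask: np.ndarray | None = None
    georef: Georeference = field(default_factory=Georeference)

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=float)
        if self.bands.ndim != 3:
            raise ValueError("bands must be a (n_bands, rows, cols) array")
        if len(self.band_names) != self.bands.shape[0]:
            raise ValueError(
                f"{len(self.band_names)} band names for {self.bands.shape[0]} bands"
            )
        if self.mask is None:
            self.mask = np.all(np.isfinite(self.bands), axis=0)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.bands.shape[1:]:
            raise ValueError("mask shape does not match band shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands.shape[1:]

    def band(self, name: str) -> np.ndarray:
        return self.bands[self.band_names.index(name)]

    def copy(self) -> "ReflectanceStack":
        return replace(self, bands=self.bands.copy(), mask=self.mask.copy())


def _description(band_names, georef: Georeference, nodata: float) -> str:
    return json.dumps(
        {
            "band_names": list(band_names),
            "nodata": nodata,
            "georef": {"x0": georef.x0, "y0": georef.y0, "cell_size": georef.cell_size},
        }
    )


def _geotags(georef: Georeference):
    scale = (georef.cell_size, georef.cell_size, 0.0)
    tiepoint = (0.0, 0.0, 0.0, georef.x0, georef.y0, 0.0)
    return [
        (33550, "d", 3, scale, True),  # ModelPixelScaleTag
        (33922, "d", 6, tiepoint, True),  # ModelTiepointTag
    ]


def write_grid(path, grid: np.ndarray, georef: Georeference = Georeference(),
               nodata: float = NODATA) -> None:
    """Write a single-band grid (NaN mapped to ``nodata``)."""
    data = np.asarray(grid, dtype=np.float32).copy()
    data[~np.isfinite(data)] = nodata
    tifffile.imwrite(
        path, data, description=_description(["value"], georef, nodata),
        extratags=_geotags(georef),
    )


def read_grid(path) -> tuple[np.ndarray, Georeference]:
    """Read a single-band grid; ``nodata`` pixels become NaN."""
    grids, names, georef, nodata = _read(path)
    return grids[0], georef


def write_stack(path, stack: ReflectanceStack, nodata: float = NODATA) -> None:
    data = np.asarray(stack.bands, dtype=np.float32).copy()
    data[:, ~stack.mask] = nodata
    data[~np.isfinite(data)] = nodata
    tifffile.imwrite(
        path, data, description=_description(stack.band_names, stack.georef, nodata),
        extratags=_geotags(stack.georef),
    )


def read_stack(path) -> ReflectanceStack:
    grids, names, georef, nodata = _read(path)
    mask = np.all(np.isfinite(grids), axis=0)
    return ReflectanceStack(grids, tuple(names), mask, georef)


def _read(path):
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray().astype(float)
        page = tif.pages[0]
        desc = page.description
        names, georef, nodata = None, Georeference(), NODATA
        if desc:
            try:
                meta = json.loads(desc)
                names = meta.get("band_names")
                g = meta.get("georef", {})
                georef = Georeference(g.get("x0", 0.0), g.get("y0", 0.0),
                                      g.get("cell_size", 1.0))
                nodata = meta.get("nodata", NODATA)
            except (json.JSONDecodeError, AttributeError):
                pass
        if georef.cell_size == 1.0 and 33550 in page.tags:
            scale = page.tags[33550].value
            tie = page.tags[33922].value if 33922 in page.tags else (0, 0, 0, 0, 0, 0)
            georef = Georeference(float(tie[3]), float(tie[4]), float(scale[0]))
    if data.ndim == 2:
        data = data[None]
    if names is None or len(names) != data.shape[0]:
        names = [f"band{i + 1}" for i in range(data.shape[0])]
    data[data == nodata] = np.nan
    return data, names, georef, nodata
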