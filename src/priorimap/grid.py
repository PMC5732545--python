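"""Georeferenced single-band raster grid.

The :class:`Grid` is the universal spatial carrier of the package: every
landscape feature mask, predictor layer and model surface is a ``Grid``.
Conventions (fixed once, used everywhere):

* origin ``(x0, y0)`` is the **top-left corner** of the top-left pixel,
  in projected metres; columns run east (+x), rows run south (−y);
* pixels are half-open: column ``c`` covers ``[x0 + c*s, x0 + (c+1)*s)``
  and row ``r`` covers ``(y0 - (r+1)*s, y0 - r*s]`` — a point exactly on a
  shared edge belongs to the pixel to the right / below, so containment is
  a plain ``floor``;
* statistics and model predictions ignore nodata pixels.

GeoTIFFs are written through :mod:`tifffile` as single-band float32 with
ModelPixelScale / ModelTiepoint / GDAL_NODATA tags, which GDAL-based GIS
tools read back with full georeferencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

NODATA_VALUE = -9999.0

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass
class Grid:
    """A single-band raster: values + pixel size + origin + nodata mask.

    Parameters
    ----------
    values : ndarray, shape (rows, cols)
        Cell values; stored as float64.
    pixel_size : float
        Side length of the square pixels, metres. Must be > 0.
    origin : tuple of float
        ``(x0, y0)`` of the top-left corner in projected metres.
    nodata : ndarray of bool, optional
        True where the pixel carries no data. Defaults to all-valid.
    """

    values: np.ndarray
    pixel_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be a 2-D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.nodata is None:
            self.nodata = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata = np.asarray(self.nodata, dtype=bool)
            if self.nodata.shape != self.values.shape:
                raise ValueError("nodata mask shape mismatch")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of data pixels (inverse of nodata)."""
        return ~self.nodata

    def aligned_with(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.pixel_size, other.pixel_size)
            and np.allclose(self.origin, other.origin)
        )

    def copy_with(self, values: np.ndarray, nodata: np.ndarray | None = None) -> "Grid":
        """New grid on the same geometry with different values."""
        return Grid(
            values=np.asarray(values, dtype=float),
            pixel_size=self.pixel_size,
            origin=self.origin,
            nodata=self.nodata.copy() if nodata is None else nodata,
        )

    # -- coordinate transforms ------------------------------------------
    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) centre coordinates as 2-D arrays matching ``values``."""
        rows, cols = self.shape
        x0, y0 = self.origin
        x = x0 + (np.arange(cols) + 0.5) * self.pixel_size
        y = y0 - (np.arange(rows) + 0.5) * self.pixel_size
        return np.meshgrid(x, y)

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the pixel containing each point (half-open rule).

        Raises ``ValueError`` if any point falls outside the extent.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        col = np.floor((x - x0) / self.pixel_size).astype(int)
        row = np.floor((y0 - y) / self.pixel_size).astype(int)
        # points exactly on the bottom y-edge of the extent round into the
        # last row by the half-open rule in y (interval open at the bottom)
        rows, cols = self.shape
        on_bottom = (y0 - y) / self.pixel_size == rows
        row = np.where(on_bottom, rows - 1, row)
        if np.any((col < 0) | (col >= cols) | (row < 0) | (row >= rows)):
            raise ValueError("point outside raster extent")
        return row, col

    def center_of(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Centre coordinates of the given pixels."""
        x0, y0 = self.origin
        x = x0 + (np.asarray(col) + 0.5) * self.pixel_size
        y = y0 - (np.asarray(row) + 0.5) * self.pixel_size
        return x, y

    # -- statistics ------------------------------------------------------
    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]


def write_geotiff(grid: Grid, path: str | Path) -> Path:
    """Write a grid as a single-band float32 GeoTIFF with nodata tag."""
    path = Path(path)
    data = grid.values.astype(np.float32)
    data = np.where(grid.nodata, np.float32(NODATA_VALUE), data)
    s = float(grid.pixel_size)
    x0, y0 = grid.origin
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (s, s, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(NODATA_VALUE)),
    ]
    tifffile.imwrite(path, data, extratags=extratags)
    return path


def read_geotiff(path: str | Path) -> Grid:
    """Read a grid written by :func:`write_geotiff` (or any single-band
    GeoTIFF with pixel-scale, tiepoint and GDAL nodata tags)."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        tags = page.tags
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value
        tiepoint = tags[_TAG_MODEL_TIEPOINT].value
        nodata_value = float(tags[_TAG_GDAL_NODATA].value)
    pixel_size = float(scale[0])
    # tiepoint maps raster (i, j, k) -> model (x, y, z); we write (0, 0)
    i, j = tiepoint[0], tiepoint[1]
    x0 = tiepoint[3] - i * pixel_size
    y0 = tiepoint[4] + j * pixel_size
    nodata = values == nodata_value
    values = np.where(nodata, np.nan, values)
    return Grid(values=values, pixel_size=pixel_size, origin=(x0, y0), nodata=nodata)


def require_aligned(*grids: Grid) -> None:
    """Raise ``ValueError`` unless all grids share geometry."""
    first = grids[0]
    for g in grids[1:]:
        if not first.aligned_with(g):
            raise ValueError("grids are not aligned (extent / pixel size / origin differ)")
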