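"""Predictor-layer construction and point extraction.

Builds the eleven-variable habitat predictor stack used by both the
occurrence and the abundance model: Euclidean distance (metres) to eight
landscape feature classes, contiguous farmland patch area (km²), and the
per-pixel mean and maximum of the monthly NDVI stack (MNNDVI / MAXNDVI).
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import Grid, read_geotiff, require_aligned, write_geotiff
from .observations import ObservationSet

logger = logging.getLogger(__name__)

#: the eight feature classes that get a distance-to-feature layer
FEATURE_CLASSES = (
    "pool",
    "river",
    "residential",
    "national_road",
    "provincial_road",
    "expressway",
    "farmland_road",
    "ditch",
)

#: canonical predictor names, in stack order
PREDICTOR_NAMES = tuple(f"dist_{c}" for c in FEATURE_CLASSES) + (
    "farmland_area",
    "mnndvi",
    "maxndvi",
)

# 4-connectivity structuring element for patch labelling
_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


class PredictorStack:
    """Ordered, aligned map ``name -> Grid`` of predictor layers."""

    def __init__(self, layers: Mapping[str, Grid]):
        if not layers:
            raise ValueError("empty predictor stack")
        self._layers: "OrderedDict[str, Grid]" = OrderedDict(layers)
        require_aligned(*self._layers.values())

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._layers)

    @property
    def template(self) -> Grid:
        """The first layer, as a geometry template."""
        return next(iter(self._layers.values()))

    def __getitem__(self, name: str) -> Grid:
        return self._layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __len__(self) -> int:
        return len(self._layers)

    def __iter__(self):
        return iter(self._layers)

    def items(self):
        return self._layers.items()

    def combined_nodata(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Pixels nodata in any of the requested layers."""
        names = self.names if names is None else names
        mask = np.zeros(self.template.shape, dtype=bool)
        for n in names:
            mask |= self._layers[n].nodata
        return mask

    def as_matrix(self, names: Sequence[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Flatten to ``(X, valid)``: feature matrix over valid pixels.

        Returns the ``n_valid x len(names)`` array and the boolean validity
        mask (True where every requested layer has data).
        """
        names = list(self.names if names is None else names)
        valid = ~self.combined_nodata(names)
        X = np.column_stack([self._layers[n].values[valid] for n in names])
        return X, valid

    def write_dir(self, out_dir: str | Path) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, grid in self._layers.items():
            paths.append(write_geotiff(grid, out_dir / f"{name}.tif"))
        return paths

    @classmethod
    def read_dir(cls, in_dir: str | Path, names: Iterable[str] = PREDICTOR_NAMES) -> "PredictorStack":
        in_dir = Path(in_dir)
        return cls({n: read_geotiff(in_dir / f"{n}.tif") for n in names})


def distance_layer(feature_mask: Grid) -> Grid:
    """Euclidean distance (m) from each pixel centre to the nearest
    feature-pixel centre; feature pixels get 0.

    Uses the exact Euclidean distance transform, so it agrees with the
    brute-force min-over-feature-pixels definition to float precision.
    """
    mask = feature_mask.values
    if not np.all(np.isin(mask[feature_mask.valid], (0, 1))):
        raise ValueError("feature mask must be binary")
    if not np.any(mask == 1):
        raise ValueError("feature mask has no feature pixels")
    dist = ndimage.distance_transform_edt(mask == 0) * feature_mask.pixel_size
    return feature_mask.copy_with(dist)


def farmland_patch_area(farmland_mask: Grid) -> Grid:
    """Area (km²) of the connected farmland patch containing each pixel.

    4-connected components; non-farmland pixels get 0.
    """
    mask = farmland_mask.values
    if not np.all(np.isin(mask[farmland_mask.valid], (0, 1))):
        raise ValueError("farmland mask must be binary")
    labels, n = ndimage.label(mask == 1, structure=_STRUCTURE_4)
    pixel_area_km2 = (farmland_mask.pixel_size ** 2) / 1e6
    sizes = np.bincount(labels.ravel(), minlength=n + 1).astype(float)
    sizes[0] = 0.0  # background
    areas = sizes[labels] * pixel_area_km2
    return farmland_mask.copy_with(areas)


def ndvi_summaries(ndvi_stack: Sequence[Grid]) -> tuple[Grid, Grid]:
    """Pixel-wise mean (MNNDVI) and maximum (MAXNDVI) over monthly NDVI.

    A pixel is nodata only where every month is nodata; otherwise the
    summaries use the available months.
    """
    if len(ndvi_stack) < 1:
        raise ValueError("need at least one NDVI layer")
    require_aligned(*ndvi_stack)
    stacked = np.ma.stack(
        [np.ma.masked_array(g.values, mask=g.nodata) for g in ndvi_stack]
    )
    mean = stacked.mean(axis=0)
    mx = stacked.max(axis=0)
    all_nodata = np.all([g.nodata for g in ndvi_stack], axis=0)
    template = ndvi_stack[0]
    mean_grid = template.copy_with(mean.filled(np.nan), nodata=all_nodata)
    max_grid = template.copy_with(mx.filled(np.nan), nodata=all_nodata)
    return mean_grid, max_grid


def build_stack(landscape) -> PredictorStack:
    """Assemble the full 11-layer predictor stack from a landscape.

    ``landscape`` provides ``feature_masks`` (one binary Grid per class in
    :data:`FEATURE_CLASSES`), ``farmland`` and ``ndvi`` — see
    :class:`priorimap.landsim.Landscape`.
    """
    layers: "OrderedDict[str, Grid]" = OrderedDict()
    for cls in FEATURE_CLASSES:
        if cls not in landscape.feature_masks:
            raise ValueError(f"landscape missing feature class {cls!r}")
        layers[f"dist_{cls}"] = distance_layer(landscape.feature_masks[cls])
    layers["farmland_area"] = farmland_patch_area(landscape.farmland)
    mean_g, max_g = ndvi_summaries(landscape.ndvi)
    layers["mnndvi"] = mean_g
    layers["maxndvi"] = max_g
    # restrict every layer to the study-area validity mask
    study = landscape.study_mask
    outside = study.values == 0
    for name, grid in layers.items():
        layers[name] = grid.copy_with(grid.values, nodata=grid.nodata | outside)
    return PredictorStack(layers)


def extract_at_points(stack: PredictorStack, points: ObservationSet) -> pd.DataFrame:
    """Sample every layer at the pixel containing each point.

    Returns the sample matrix: one row per retained point with columns
    ``point_id, x, y``, one column per predictor, plus the responses
    ``presence`` and ``count``. Rows touching nodata in any predictor are
    dropped (count logged).
    """
    template = stack.template
    row, col = template.index_of(points.x, points.y)
    data: dict[str, np.ndarray] = {
        "point_id": points.point_id,
        "x": points.x,
        "y": points.y,
    }
    bad = np.zeros(len(points), dtype=bool)
    for name, grid in stack.items():
        data[name] = grid.values[row, col]
        bad |= grid.nodata[row, col]
    data["presence"] = points.presence
    data["count"] = points.count
    df = pd.DataFrame(data)
    if bad.any():
        logger.info("extract_at_points: dropped %d rows with nodata predictors", int(bad.sum()))
        df = df.loc[~bad].reset_index(drop=True)
    return df
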