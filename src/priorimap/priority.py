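"""Priority protection index and surface export.

The priority protection index combines the occurrence and abundance
surfaces pixel-wise::

    PI = (RIO × RA) / max(RIO × RA)

an index in [0, 1] whose maximum marks the cell where high occurrence
and high abundance coincide. The normalisation makes PI invariant to any
positive rescaling of RA, so only the *relative* abundance pattern
matters.

Inverse distance weighting (IDW) provides the cosmetic smoothing of
lattice predictions for mapping: an exact interpolator whose value at a
query point is the ``d^(−p)``-weighted mean of the k nearest samples.
The PI arithmetic always uses the unsmoothed pixel values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from .grid import Grid, require_aligned, write_geotiff


def compute_pi(rio: Grid, ra: Grid) -> Grid:
    """Pixel-wise ``(RIO·RA) / max(RIO·RA)`` over valid pixels.

    Raises ``ValueError`` if every product is zero (the index is 0/0 —
    returning an all-zero map would silently claim "no priority
    anywhere").
    """
    require_aligned(rio, ra)
    nodata = rio.nodata | ra.nodata
    valid = ~nodata
    rio_v = rio.values
    ra_v = ra.values
    if valid.any():
        if np.nanmin(rio_v[valid]) < 0 or np.nanmax(rio_v[valid]) > 1:
            raise ValueError("RIO values must lie in [0, 1]")
        if np.nanmin(ra_v[valid]) < 0:
            raise ValueError("RA values must be >= 0")
    product = rio_v * ra_v
    max_product = product[valid].max() if valid.any() else 0.0
    if not max_product > 0:
        raise ValueError("all RIO×RA products are zero; PI is undefined")
    pi = np.where(valid, product / max_product, np.nan)
    return rio.copy_with(pi, nodata=nodata)


@dataclass
class IdwParams:
    """IDW settings: power ``p`` > 0, neighbourhood size ``k`` >= 1, and
    an optional output pixel size (defaults to the target template's)."""

    power: float = 2.0
    n_neighbors: int = 12
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        if self.power <= 0:
            raise ValueError("IDW power must be > 0")
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")


class IdwInterpolator(BaseEstimator):
    """Exact inverse-distance-weighting interpolator (sklearn-style).

    ``fit(XY, values)`` stores the sample points; ``predict(XY)`` returns
    the ``d^(−p)``-weighted mean of the ``n_neighbors`` nearest samples,
    exactly reproducing a sample's value when queried at its location.
    """

    def __init__(self, power: float = 2.0, n_neighbors: int = 12):
        self.power = power
        self.n_neighbors = n_neighbors

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be an (n, 2) array of coordinates")
        if len(X) == 0:
            raise ValueError("need at least one sample point")
        if self.n_neighbors > len(X):
            raise ValueError("n_neighbors exceeds the number of sample points")
        IdwParams(power=self.power, n_neighbors=self.n_neighbors)  # validate
        self.tree_ = cKDTree(X)
        self.values_ = y
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        dist, idx = self.tree_.query(X, k=self.n_neighbors)
        if self.n_neighbors == 1:
            dist = dist[:, None]
            idx = idx[:, None]
        vals = self.values_[idx]
        exact = dist[:, 0] == 0.0  # query coincides with a sample point
        with np.errstate(divide="ignore"):
            w = dist ** (-self.power)
        w[~np.isfinite(w)] = 0.0
        num = (w * vals).sum(axis=1)
        den = w.sum(axis=1)
        out = np.empty(len(X))
        nz = den > 0
        out[nz] = num[nz] / den[nz]
        out[exact] = vals[exact, 0]
        out[~nz & ~exact] = vals[~nz & ~exact].mean(axis=1)  # all-zero weights fallback
        return out


def idw_smooth(points: Sequence[tuple[float, float, float]] | np.ndarray,
               params: IdwParams, target: Grid) -> Grid:
    """Interpolate scattered ``(x, y, value)`` samples onto a grid."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) == 0:
        raise ValueError("points must be a non-empty (n, 3) array of (x, y, value)")
    interp = IdwInterpolator(power=params.power, n_neighbors=params.n_neighbors)
    interp.fit(pts[:, :2], pts[:, 2])
    if params.pixel_size is not None and params.pixel_size != target.pixel_size:
        rows = int(round(target.shape[0] * target.pixel_size / params.pixel_size))
        cols = int(round(target.shape[1] * target.pixel_size / params.pixel_size))
        target = Grid(values=np.zeros((rows, cols)), pixel_size=params.pixel_size,
                      origin=target.origin)
    gx, gy = target.pixel_centers()
    query = np.column_stack([gx.ravel(), gy.ravel()])
    out = interp.predict(query).reshape(target.shape)
    out = np.where(target.nodata, np.nan, out)
    return target.copy_with(out)


def smooth_grid(grid: Grid, params: IdwParams | None = None) -> Grid:
    """IDW-smooth a prediction surface through its own valid pixel centres
    (the map-cosmetics step; the PI math stays on the raw values)."""
    params = params or IdwParams()
    gx, gy = grid.pixel_centers()
    valid = grid.valid & np.isfinite(grid.values)
    pts = np.column_stack([gx[valid], gy[valid], grid.values[valid]])
    k = min(params.n_neighbors, len(pts))
    return idw_smooth(pts, IdwParams(power=params.power, n_neighbors=k,
                                     pixel_size=params.pixel_size), grid)


@dataclass
class SurfaceBundle:
    """The exportable model surfaces: RIO, raw & adjusted RA, and PI."""

    rio: Grid
    ra_raw: Grid
    ra_adjusted: Grid
    pi: Grid
    smoothed: dict = field(default_factory=dict)  # name -> Grid (optional)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("rio", "ra_raw", "ra_adjusted", "pi"):
            if getattr(self, name) is None:
                raise ValueError(f"bundle missing surface {name!r}")
        require_aligned(self.rio, self.ra_raw, self.ra_adjusted, self.pi)


def _grid_hash(grid: Grid) -> str:
    h = hashlib.md5()
    h.update(np.ascontiguousarray(grid.values.astype(np.float32)).tobytes())
    return h.hexdigest()


def export_bundle(bundle: SurfaceBundle, out_dir: str | Path) -> list[Path]:
    """Write rio/ra_adjusted/pi (plus extras) as GeoTIFFs with a JSON
    provenance sidecar recording seeds, surface hashes and max(RIO·RA)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = [
        write_geotiff(bundle.rio, out_dir / "rio.tif"),
        write_geotiff(bundle.ra_raw, out_dir / "ra_raw.tif"),
        write_geotiff(bundle.ra_adjusted, out_dir / "ra_adjusted.tif"),
        write_geotiff(bundle.pi, out_dir / "pi.tif"),
    ]
    for name, grid in bundle.smoothed.items():
        paths.append(write_geotiff(grid, out_dir / f"{name}_smooth.tif"))
    valid = bundle.rio.valid & bundle.ra_adjusted.valid
    product = bundle.rio.values[valid] * bundle.ra_adjusted.values[valid]
    sidecar = {
        "max_product": float(product.max()) if product.size else 0.0,
        "surfaces": {
            "rio": _grid_hash(bundle.rio),
            "ra_raw": _grid_hash(bundle.ra_raw),
            "ra_adjusted": _grid_hash(bundle.ra_adjusted),
            "pi": _grid_hash(bundle.pi),
        },
        **bundle.provenance,
    }
    sidecar_path = out_dir / "bundle.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    paths.append(sidecar_path)
    return paths
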