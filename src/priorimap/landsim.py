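"""Synthetic landscape and virtual-species generator.

Emulates an agricultural coastal-plain study system: a ~2,200 km² extent
of 30 m pixels dominated by winter-cereal farmland, criss-crossed by
roads, rivers and irrigation ditches, dotted with villages and open-water
pools, plus a stack of monthly winter NDVI fields. A configurable virtual
species responds to the derived predictor layers through plateau-shaped
preference kernels (a flat preferred range with a constant penalty
outside), separately for occurrence probability and expected flock size,
so every downstream modelling stage can be tested against known truth.

All randomness flows from one integer seed through a fixed
``numpy.random.SeedSequence`` spawning order (farmland field, one stream
per feature class, NDVI months), so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from scipy import ndimage
from skimage import draw

from .grid import Grid, read_geotiff, write_geotiff
from .layers import FEATURE_CLASSES, PredictorStack, build_stack
from .observations import ObservationSet

# feature classes rendered as random blobs; all others are polylines
_BLOB_CLASSES = {"pool", "residential"}
# perpendicular wiggle of polyline classes, as a fraction of the extent
_WIGGLE = {
    "river": 0.15,
    "ditch": 0.10,
    "national_road": 0.02,
    "provincial_road": 0.02,
    "expressway": 0.01,
    "farmland_road": 0.04,
}
# blob radius range in pixels (min, max)
_BLOB_RADIUS = {"pool": (1, 4), "residential": (2, 8)}

#: default feature counts for the full-scale (~2,200 km²) landscape
DEFAULT_FEATURE_COUNTS = {
    "pool": 40,
    "river": 8,
    "residential": 150,
    "national_road": 2,
    "provincial_road": 3,
    "expressway": 2,
    "farmland_road": 200,
    "ditch": 80,
}


@dataclass
class LandscapeConfig:
    """Geometry and feature intensities of a synthetic landscape.

    Defaults describe the full study-system scale: 1,560 × 1,560 pixels of
    30 m (≈ 2,190 km²), five winter NDVI months, and feature counts that
    give distance fields with realistic ranges. Tests and demos shrink
    ``extent_pixels`` and scale the counts down.
    """

    extent_pixels: tuple[int, int] = (1560, 1560)
    pixel_size: float = 30.0
    feature_counts: dict = field(default_factory=lambda: dict(DEFAULT_FEATURE_COUNTS))
    farmland_fraction: float = 0.764  # landscape share of farmland
    ndvi_months: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.extent_pixels
        if rows < 1 or cols < 1:
            raise ValueError("extent must be at least 1x1 pixels")
        if not 0.0 <= self.farmland_fraction <= 1.0:
            raise ValueError("farmland_fraction must be in [0, 1]")
        if self.ndvi_months < 1:
            raise ValueError("ndvi_months must be >= 1")
        unknown = set(self.feature_counts) - set(FEATURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")
        for cls, n in self.feature_counts.items():
            if n < 0:
                raise ValueError(f"negative count for {cls!r}")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = asdict(self)
        d["extent_pixels"] = list(self.extent_pixels)
        path.write_text(yaml.safe_dump(d))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LandscapeConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["extent_pixels"] = tuple(d["extent_pixels"])
        return cls(**d)


@dataclass
class PlateauKernel:
    """Flat preference range [low, high] with constant penalty outside.

    ``k(v) = 1`` for ``low <= v <= high`` and ``k(v) = outside``
    otherwise — the range-shaped response a partial-dependence plot of a
    habitat-preference model typically shows.
    """

    low: float
    high: float
    outside: float = 0.0

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("plateau edges must satisfy low < high")
        if not 0.0 <= self.outside <= 1.0:
            raise ValueError("outside penalty must be in [0, 1]")

    def __call__(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        return np.where((v >= self.low) & (v <= self.high), 1.0, self.outside)


@dataclass
class ResponseConfig:
    """Virtual-species response: occurrence and abundance kernels.

    Occurrence probability is the product of the per-predictor occurrence
    kernels, rescaled so its maximum over the landscape is 1. Expected
    flock size is ``lambda_scale`` times the product of the abundance
    kernels. Counts are drawn overdispersed with variance =
    ``dispersion * mean`` (Poisson when ``dispersion == 1``).
    """

    occurrence: Mapping[str, PlateauKernel]
    abundance: Mapping[str, PlateauKernel]
    lambda_scale: float = 20.0
    dispersion: float = 4.0
    n_sites: int = 94

    def __post_init__(self) -> None:
        if self.lambda_scale < 0:
            raise ValueError("lambda_scale must be >= 0")
        if self.dispersion < 1.0:
            raise ValueError("dispersion (variance inflation) must be >= 1")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")

    def to_yaml(self, path: str | Path) -> Path:
        d = {
            "occurrence": {k: asdict(v) for k, v in self.occurrence.items()},
            "abundance": {k: asdict(v) for k, v in self.abundance.items()},
            "lambda_scale": self.lambda_scale,
            "dispersion": self.dispersion,
            "n_sites": self.n_sites,
        }
        path = Path(path)
        path.write_text(yaml.safe_dump(d))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ResponseConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(
            occurrence={k: PlateauKernel(**v) for k, v in d["occurrence"].items()},
            abundance={k: PlateauKernel(**v) for k, v in d["abundance"].items()},
            lambda_scale=d["lambda_scale"],
            dispersion=d["dispersion"],
            n_sites=d["n_sites"],
        )


@dataclass
class Landscape:
    """Generated landscape: feature masks, farmland, NDVI stack, validity."""

    feature_masks: dict[str, Grid]
    farmland: Grid
    ndvi: list[Grid]
    study_mask: Grid
    config: LandscapeConfig | None = None

    def write_dir(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for cls, grid in self.feature_masks.items():
            write_geotiff(grid, out_dir / f"mask_{cls}.tif")
        write_geotiff(self.farmland, out_dir / "farmland.tif")
        for i, g in enumerate(self.ndvi):
            write_geotiff(g, out_dir / f"ndvi_{i:02d}.tif")
        write_geotiff(self.study_mask, out_dir / "study_mask.tif")
        if self.config is not None:
            self.config.to_yaml(out_dir / "landscape.yaml")
        return out_dir

    @classmethod
    def read_dir(cls, in_dir: str | Path) -> "Landscape":
        in_dir = Path(in_dir)
        masks = {c: read_geotiff(in_dir / f"mask_{c}.tif") for c in FEATURE_CLASSES}
        ndvi = sorted(in_dir.glob("ndvi_*.tif"))
        cfg_path = in_dir / "landscape.yaml"
        return cls(
            feature_masks=masks,
            farmland=read_geotiff(in_dir / "farmland.tif"),
            ndvi=[read_geotiff(p) for p in ndvi],
            study_mask=read_geotiff(in_dir / "study_mask.tif"),
            config=LandscapeConfig.from_yaml(cfg_path) if cfg_path.exists() else None,
        )


# ---------------------------------------------------------------------------
# landscape generation


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Spatially autocorrelated standard field: smoothed white noise,
    re-standardised to zero mean / unit sd."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    sd = f.std()
    if sd > 0:
        f = (f - f.mean()) / sd
    return f


def _draw_blobs(rng: np.random.Generator, shape: tuple[int, int], n: int,
                radius_range: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=float)
    rows, cols = shape
    lo, hi = radius_range
    for _ in range(n):
        r = rng.integers(0, rows)
        c = rng.integers(0, cols)
        radius = rng.integers(lo, hi + 1)
        rr, cc = draw.disk((r, c), radius, shape=shape)
        mask[rr, cc] = 1.0
    return mask


def _draw_polyline(rng: np.random.Generator, shape: tuple[int, int], wiggle: float) -> np.ndarray:
    """One 1-pixel-wide polyline crossing the extent, with perpendicular
    jitter proportional to ``wiggle``."""
    mask = np.zeros(shape, dtype=float)
    rows, cols = shape
    horizontal = rng.random() < 0.5
    length = cols if horizontal else rows
    breadth = rows if horizontal else cols
    n_vert = max(2, int(length / max(1, length // 6)))  # ~6 segments
    along = np.linspace(0, length - 1, n_vert)
    base = rng.uniform(0, breadth)
    drift = rng.uniform(-0.3, 0.3) * breadth
    across = base + np.linspace(0, drift, n_vert) + rng.normal(0, wiggle * breadth, n_vert)
    across = np.clip(across, 0, breadth - 1)
    pts = []
    for a, b in zip(along, across):
        if horizontal:
            pts.append((int(round(b)), int(round(a))))
        else:
            pts.append((int(round(a)), int(round(b))))
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = draw.line(r0, c0, r1, c1)
        mask[rr, cc] = 1.0
    return mask


def _draw_lines(rng: np.random.Generator, shape: tuple[int, int], n: int, wiggle: float) -> np.ndarray:
    mask = np.zeros(shape, dtype=float)
    for _ in range(n):
        mask = np.maximum(mask, _draw_polyline(rng, shape, wiggle))
    return mask


def generate_landscape(config: LandscapeConfig) -> Landscape:
    """Generate a synthetic landscape from a config; deterministic per seed.

    Farmland is a thresholded smoothed Gaussian field whose threshold is
    the empirical quantile, so the realised farmland proportion matches
    ``farmland_fraction`` exactly up to pixel discreteness. Linear feature
    classes are rasterised random polylines (1 pixel wide); pools and
    residential areas are random disks. NDVI months are smoothed noise
    fields lifted on farmland (winter cereal) with a mild seasonal drift,
    clipped to [−1, 1].
    """
    shape = tuple(config.extent_pixels)
    if shape[0] * shape[1] == 0:
        raise ValueError("zero-area extent")
    seeds = np.random.SeedSequence(config.seed).spawn(2 + len(FEATURE_CLASSES))
    rng_farm = np.random.default_rng(seeds[0])
    rng_ndvi = np.random.default_rng(seeds[1])
    feature_rngs = {
        cls: np.random.default_rng(s) for cls, s in zip(FEATURE_CLASSES, seeds[2:])
    }

    def make_grid(values: np.ndarray) -> Grid:
        return Grid(values=values, pixel_size=config.pixel_size, origin=(0.0, 0.0))

    # farmland: exact-fraction threshold of a smooth field
    sigma = max(2.0, min(shape) / 20.0)
    if config.farmland_fraction >= 1.0:
        farm = np.ones(shape)
    elif config.farmland_fraction <= 0.0:
        farm = np.zeros(shape)
    else:
        f = _smooth_field(rng_farm, shape, sigma)
        thresh = np.quantile(f, 1.0 - config.farmland_fraction)
        farm = (f > thresh).astype(float)

    masks: dict[str, Grid] = {}
    for cls in FEATURE_CLASSES:
        n = int(config.feature_counts.get(cls, 0))
        rng = feature_rngs[cls]
        if n == 0:
            m = np.zeros(shape)
        elif cls in _BLOB_CLASSES:
            m = _draw_blobs(rng, shape, n, _BLOB_RADIUS[cls])
        else:
            m = _draw_lines(rng, shape, n, _WIGGLE[cls])
        if n > 0 and not m.any():
            raise RuntimeError(f"could not place any {cls!r} feature")
        masks[cls] = make_grid(m)

    # monthly NDVI: farmland lift + autocorrelated noise + seasonal drift
    months = config.ndvi_months
    drift = np.linspace(-0.04, 0.06, months)
    ndvi = []
    for m in range(months):
        noise = _smooth_field(rng_ndvi, shape, sigma / 2.0) * 0.05
        vals = 0.06 + 0.09 * farm + noise + drift[m]
        ndvi.append(make_grid(np.clip(vals, -1.0, 1.0)))

    return Landscape(
        feature_masks=masks,
        farmland=make_grid(farm),
        ndvi=ndvi,
        study_mask=make_grid(np.ones(shape)),
        config=config,
    )


# ---------------------------------------------------------------------------
# virtual-species truth and observation simulation


def _evaluate_kernels(kernels: Mapping[str, PlateauKernel], stack: PredictorStack) -> np.ndarray:
    out = np.ones(stack.template.shape)
    for name, kernel in kernels.items():
        if name not in stack:
            raise ValueError(f"response references unknown predictor {name!r}")
        out = out * kernel(stack[name].values)
    return out


def true_surfaces(
    landscape: Landscape,
    response: ResponseConfig,
    stack: PredictorStack | None = None,
) -> tuple[Grid, Grid]:
    """True occurrence probability p and expected count λ, pixel-wise.

    p is the product of occurrence kernels scaled to maximum 1 over valid
    pixels; λ is ``lambda_scale`` × product of abundance kernels.
    """
    if stack is None:
        stack = build_stack(landscape)
    template = stack.template
    p = _evaluate_kernels(response.occurrence, stack)
    nodata = stack.combined_nodata()
    valid = ~nodata
    pmax = p[valid].max() if valid.any() else 0.0
    if pmax > 0:
        p = p / pmax
    lam = response.lambda_scale * _evaluate_kernels(response.abundance, stack)
    p_grid = template.copy_with(p, nodata=nodata.copy())
    lam_grid = template.copy_with(lam, nodata=nodata.copy())
    return p_grid, lam_grid


def _truncated_overdispersed_count(
    rng: np.random.Generator, lam: float, dispersion: float
) -> int:
    """One count >= 1 with mean ≈ lam and variance ≈ dispersion × lam.

    Gamma-mixed Poisson (negative-binomial type); rejection of zeros keeps
    presence points consistent with having observed a flock.
    """
    lam = max(lam, 1e-9)
    for _ in range(1000):
        if dispersion <= 1.0:
            c = rng.poisson(lam)
        else:
            shape = lam / (dispersion - 1.0)
            c = rng.poisson(rng.gamma(shape, dispersion - 1.0))
        if c >= 1:
            return int(c)
    return 1


def simulate_observations(
    landscape: Landscape,
    response: ResponseConfig,
    seed: int,
    stack: PredictorStack | None = None,
) -> ObservationSet:
    """Draw presence sites ∝ p with overdispersed counts of mean λ.

    Sites are distinct valid pixels sampled without replacement with
    probability proportional to the true occurrence surface; each gets a
    zero-truncated overdispersed count with the local expected flock size.
    Points sit at pixel centres. Deterministic given ``seed``.
    """
    if stack is None:
        stack = build_stack(landscape)
    p_grid, lam_grid = true_surfaces(landscape, response, stack=stack)
    valid = p_grid.valid
    p = p_grid.values.copy()
    p[~valid] = 0.0
    flat = p.ravel()
    total = flat.sum()
    if total <= 0:
        raise ValueError("occurrence probability is identically zero")
    n_valid = int(np.count_nonzero(flat))
    if response.n_sites > n_valid:
        raise ValueError("n_sites exceeds the number of pixels with positive p")
    rng = np.random.default_rng(seed)
    idx = rng.choice(flat.size, size=response.n_sites, replace=False, p=flat / total)
    rows, cols = np.unravel_index(idx, p.shape)
    x, y = p_grid.center_of(rows, cols)
    counts = np.array(
        [
            _truncated_overdispersed_count(rng, lam_grid.values[r, c], response.dispersion)
            for r, c in zip(rows, cols)
        ]
    )
    return ObservationSet(
        x=x,
        y=y,
        count=counts,
        presence=np.ones(response.n_sites, dtype=int),
        provenance="synthetic",
    )
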