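"""Diagnostics and report artefacts.

Exports the tabular material a modelling run produces: validation metrics
(ROC, RMSE, R², adjustment coefficients), predictor importance rankings,
partial-dependence curves, the presence-vs-background predictor
comparison, the land-cover composition of the study area, and the
occurrence–abundance relation curve (mean observed flock size per RIO
bin). All floats are serialised to 6 significant digits and no artefact
embeds a timestamp, so regenerating a report from the same inputs is
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import Grid
from .observations import ObservationSet


def _fmt(x: float) -> str:
    return f"{float(x):.6g}"


# ---------------------------------------------------------------------------
# land-cover composition


def composition_percentages(areas_km2: Mapping[str, float], total_km2: float) -> dict[str, float]:
    """Percentage of the study area covered by each land-cover class."""
    if total_km2 <= 0:
        raise ValueError("total area must be positive")
    return {name: 100.0 * a / total_km2 for name, a in areas_km2.items()}


def landscape_composition(landscape) -> dict[str, float]:
    """Class areas (km²) of a synthetic landscape from its masks.

    Farmland and residential come from their masks; open water is the
    union of pools and rivers. Classes may overlap by construction, so
    the shares are reported independently of one another.
    """
    px_km2 = (landscape.farmland.pixel_size ** 2) / 1e6
    water = (
        (landscape.feature_masks["pool"].values > 0)
        | (landscape.feature_masks["river"].values > 0)
    )
    return {
        "farmland": float((landscape.farmland.values > 0).sum()) * px_km2,
        "residential": float((landscape.feature_masks["residential"].values > 0).sum()) * px_km2,
        "open_water": float(water.sum()) * px_km2,
        "total": float((landscape.study_mask.values > 0).sum()) * px_km2,
    }


# ---------------------------------------------------------------------------
# occurrence–abundance relation


@dataclass
class RelationCurve:
    """Mean observed count per RIO bin, plus the raw scatter pairs."""

    bin_centers: np.ndarray
    mean_count: np.ndarray  # NaN for empty bins
    n_points: np.ndarray
    scatter: pd.DataFrame  # columns rio, count

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rio_bin_center": self.bin_centers,
                "mean_observed_count": self.mean_count,
                "n_points": self.n_points,
            }
        )


def occurrence_abundance_relation(rio: Grid, observations: ObservationSet,
                                  n_bins: int = 10) -> RelationCurve:
    """Bin RIO at the presence points into equal-width bins on [0, 1] and
    report the mean observed flock size per bin."""
    pres = observations.presence == 1
    if not pres.any():
        raise ValueError("no presence points")
    row, col = rio.index_of(observations.x[pres], observations.y[pres])
    rio_vals = rio.values[row, col]
    counts = observations.count[pres].astype(float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    # right-closed last bin so RIO == 1 lands in the top bin
    which = np.clip(np.digitize(rio_vals, edges[1:-1]), 0, n_bins - 1)
    mean_count = np.full(n_bins, np.nan)
    n_points = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        in_bin = which == b
        n_points[b] = int(in_bin.sum())
        if n_points[b]:
            mean_count[b] = counts[in_bin].mean()
    centers = (edges[:-1] + edges[1:]) / 2.0
    scatter = pd.DataFrame({"rio": rio_vals, "count": counts})
    return RelationCurve(bin_centers=centers, mean_count=mean_count,
                         n_points=n_points, scatter=scatter)


# ---------------------------------------------------------------------------
# presence vs background predictor comparison


def predictor_comparison(samples: pd.DataFrame, predictor_names: Sequence[str]) -> pd.DataFrame:
    """Mean ± sd (n−1 denominator) of each predictor at presence vs
    background points — the study-system summary table."""
    pres = samples[samples["presence"] == 1]
    back = samples[samples["presence"] == 0]
    rows = []
    for name in predictor_names:
        rows.append(
            {
                "variable": name,
                "presence_mean": pres[name].mean(),
                "presence_sd": pres[name].std(ddof=1),
                "background_mean": back[name].mean(),
                "background_sd": back[name].std(ddof=1),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report rendering


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False, float_format="%.6g")
    return path


def render_report(
    out_dir: str | Path,
    metrics: Mapping[str, float],
    importance: Mapping[str, Sequence[tuple[str, float]]],
    pd_curves: Mapping[str, Sequence[tuple[float, float]]] | None = None,
    relation: RelationCurve | None = None,
    comparison: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write metrics.json, importance.csv, pd_curves.csv, relation.csv,
    comparison.csv and summary.md into ``out_dir``.

    ``importance`` maps model name ("occurrence"/"abundance") to its
    ranking; ``pd_curves`` maps "model:variable" to a curve.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rounded = {k: float(_fmt(v)) for k, v in metrics.items()}
    paths["metrics"] = out_dir / "metrics.json"
    paths["metrics"].write_text(json.dumps(rounded, indent=2, sort_keys=True))

    imp_rows = []
    for model_name, ranking in importance.items():
        for rank, (var, score) in enumerate(ranking, start=1):
            imp_rows.append({"model": model_name, "rank": rank,
                             "variable": var, "importance": score})
    paths["importance"] = _write_csv(pd.DataFrame(imp_rows), out_dir / "importance.csv")

    if pd_curves:
        pd_rows = []
        for key, curve in pd_curves.items():
            for value, response in curve:
                pd_rows.append({"curve": key, "value": value, "response": response})
        paths["pd_curves"] = _write_csv(pd.DataFrame(pd_rows), out_dir / "pd_curves.csv")

    if relation is not None:
        paths["relation"] = _write_csv(relation.to_frame(), out_dir / "relation.csv")
        paths["relation_scatter"] = _write_csv(
            relation.scatter, out_dir / "relation_scatter.csv"
        )

    if comparison is not None:
        paths["comparison"] = _write_csv(comparison, out_dir / "comparison.csv")

    lines = ["# Model run summary", "", "## Metrics", ""]
    for k in sorted(rounded):
        lines.append(f"- {k}: {_fmt(rounded[k])}")
    lines += ["", "## Variable importance", ""]
    for model_name, ranking in importance.items():
        lines.append(f"### {model_name}")
        for rank, (var, score) in enumerate(ranking, start=1):
            lines.append(f"{rank}. {var} ({_fmt(score)})")
        lines.append("")
    paths["summary"] = out_dir / "summary.md"
    paths["summary"].write_text("\n".join(lines))
    return paths
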