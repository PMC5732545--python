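"""Point observations of flocks: coordinates, presence flag, count."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: allowed provenance tags
PROVENANCES = ("field", "synthetic", "pseudo-absence")


@dataclass
class ObservationSet:
    """Flock observation points.

    Coordinates are projected metres (pixel-centre convention when the
    points were generated on a raster). ``presence == 1`` implies
    ``count >= 1`` for field/synthetic points; pseudo-absence points carry
    ``presence == 0, count == 0``.
    """

    x: np.ndarray
    y: np.ndarray
    count: np.ndarray
    presence: np.ndarray
    provenance: str = "synthetic"
    point_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.count = np.asarray(self.count, dtype=int)
        self.presence = np.asarray(self.presence, dtype=int)
        n = len(self.x)
        if not (len(self.y) == len(self.count) == len(self.presence) == n):
            raise ValueError("coordinate/count/presence arrays must share length")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if np.any(self.count < 0):
            raise ValueError("counts must be non-negative")
        if self.provenance == "pseudo-absence":
            if np.any(self.presence != 0) or np.any(self.count != 0):
                raise ValueError("pseudo-absence points must have presence 0, count 0")
        else:
            if np.any((self.presence == 1) & (self.count < 1)):
                raise ValueError("presence points must have count >= 1")
        if self.point_id is None:
            self.point_id = np.arange(n)
        else:
            self.point_id = np.asarray(self.point_id)

    def __len__(self) -> int:
        return len(self.x)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "point_id": self.point_id,
                "x": self.x,
                "y": self.y,
                "count": self.count,
                "presence": self.presence,
                "provenance": self.provenance,
            }
        )

    def to_csv(self, path: str | Path) -> Path:
        """Write as CSV with columns x, y, count (plus bookkeeping columns)."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "ObservationSet":
        df = pd.read_csv(path)
        provenance = df["provenance"].iloc[0] if "provenance" in df else "field"
        presence = df["presence"] if "presence" in df else (df["count"] > 0).astype(int)
        return cls(
            x=df["x"].to_numpy(),
            y=df["y"].to_numpy(),
            count=df["count"].to_numpy(),
            presence=np.asarray(presence),
            provenance=str(provenance),
            point_id=df["point_id"].to_numpy() if "point_id" in df else None,
        )


def concat_observations(a: ObservationSet, b: ObservationSet) -> pd.DataFrame:
    """Stack two observation sets into one frame (provenance per row)."""
    fa, fb = a.to_frame(), b.to_frame()
    fb = fb.copy()
    fb["point_id"] = fb["point_id"] + len(fa)
    return pd.concat([fa, fb], ignore_index=True)
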