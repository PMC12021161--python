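"""Per-tile nearest-distance covariates to road and water polyline networks.

Distances are planar Euclidean meters; real-world inputs must already be in a
projected CRS (geodesic distance is out of scope).  Each tile's distance is
measured from its center point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, MultiLineString, Point, shape


@dataclass
class InfrastructureSet:
    """A set of polylines of one kind (roads or waterways)."""

    lines: list[np.ndarray]
    kind: str  # "road" | "water"

    def __post_init__(self) -> None:
        cleaned = []
        for line in self.lines:
            arr = np.asarray(line, dtype=float)
            if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] != 2:
                raise ValueError("each polyline needs >= 2 (x, y) vertices")
            if not np.all(np.isfinite(arr)):
                raise ValueError("polyline coordinates must be finite")
            cleaned.append(arr)
        self.lines = cleaned
        self._geom = MultiLineString([LineString(a) for a in cleaned]) if cleaned else None

    @property
    def geometry(self) -> MultiLineString:
        if self._geom is None:
            raise ValueError(f"empty {self.kind} infrastructure set")
        return self._geom

    def __len__(self) -> int:
        return len(self.lines)


@dataclass(frozen=True)
class DistanceRecord:
    tile_id: str
    d_road: float
    d_water: float


def nearest_distance(point_xy: tuple[float, float], infra: InfrastructureSet) -> float:
    """Minimum Euclidean point-to-segment distance over all polylines, meters."""
    if len(infra) == 0:
        raise ValueError(f"cannot compute distance to empty {infra.kind} set")
    return float(Point(point_xy).distance(infra.geometry))


def nearest_distances(points_xy: np.ndarray, infra: InfrastructureSet) -> np.ndarray:
    """Vectorized nearest distance for an (n, 2) array of points."""
    if len(infra) == 0:
        raise ValueError(f"cannot compute distance to empty {infra.kind} set")
    geom = infra.geometry
    import shapely
    pts = shapely.points(np.asarray(points_xy, dtype=float))
    return shapely.distance(pts, geom)


def compute_distance_features(manifest: pd.DataFrame,
                              roads: InfrastructureSet,
                              waters: InfrastructureSet) -> pd.DataFrame:
    """One (tile_id, d_road_m, d_water_m) record per manifest row, order-preserving.

    The manifest needs ``tile_id``, ``x_m`` and ``y_m`` columns; a missing or
    non-finite coordinate raises an error naming the offending tile.
    """
    for col in ("tile_id", "x_m", "y_m"):
        if col not in manifest.columns:
            raise ValueError(f"manifest missing required column {col!r}")
    bad = manifest[~np.isfinite(manifest["x_m"]) | ~np.isfinite(manifest["y_m"])]
    if len(bad):
        raise ValueError(f"tile {bad['tile_id'].iloc[0]!r} has missing coordinates")
    pts = manifest[["x_m", "y_m"]].to_numpy(dtype=float)
    return pd.DataFrame({
        "tile_id": manifest["tile_id"].to_numpy(),
        "d_road_m": nearest_distances(pts, roads),
        "d_water_m": nearest_distances(pts, waters),
    })


# --- IO ------------------------------------------------------------------

def read_infrastructure(path: str | Path, kind: str) -> InfrastructureSet:
    """Read LineString/MultiLineString features from a GeoJSON file."""
    data = json.loads(Path(path).read_text())
    feats = data["features"] if data.get("type") == "FeatureCollection" else [data]
    lines: list[np.ndarray] = []
    for feat in feats:
        geom = shape(feat["geometry"] if "geometry" in feat else feat)
        if geom.geom_type == "LineString":
            lines.append(np.asarray(geom.coords))
        elif geom.geom_type == "MultiLineString":
            lines.extend(np.asarray(g.coords) for g in geom.geoms)
        else:
            raise ValueError(f"unsupported geometry type {geom.geom_type}")
    return InfrastructureSet(lines, kind)


def write_infrastructure(infra: InfrastructureSet, path: str | Path) -> None:
    features = [{
        "type": "Feature",
        "properties": {"kind": infra.kind},
        "geometry": {"type": "LineString",
                     "coordinates": [[float(x), float(y)] for x, y in line]},
    } for line in infra.lines]
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}))


def write_distance_records(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)
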