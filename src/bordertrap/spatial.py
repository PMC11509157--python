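"""Border geometry, distance matrices and the per-point catch index.

All geometry is planar in meters. Orchard extents are well under 2 km, so
lon/lat inputs can be flattened with a local equirectangular projection
about the centroid without measurable error; no geodesic machinery is used.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from shapely.geometry import LineString, Point

EARTH_RADIUS_M = 6_371_000.0


@dataclass(frozen=True)
class BorderPolyline:
    """Ordered border vertices (meters); the trap-side orchard edge."""

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 2:
            raise ValueError("border polyline needs at least 2 vertices")
        for a, b in zip(self.vertices, self.vertices[1:]):
            if a == b:
                raise ValueError("consecutive border vertices must be distinct")

    @property
    def line(self) -> LineString:
        return LineString(self.vertices)


@dataclass
class TrapRecord:
    """One trap: position plus catch counts by date x sex x part.

    ``catches`` maps (date, sex, part) -> count, sex in {male, female},
    part in {sail, bin}.
    """

    id: str
    x: float
    y: float
    catches: dict[tuple[str, str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, v in self.catches.items():
            if v < 0:
                raise ValueError(f"trap {self.id}: negative catch at {key}")

    @property
    def total_catch(self) -> int:
        return sum(self.catches.values())

    def total_by(self, sex: str | None = None, part: str | None = None,
                 date: str | None = None) -> int:
        return sum(
            v for (d, s, p), v in self.catches.items()
            if (date is None or d == date)
            and (sex is None or s == sex)
            and (part is None or p == part)
        )


def min_distance_to_border(
    point: tuple[float, float], border: BorderPolyline
) -> float:
    """Minimum Euclidean distance from a point to the border polyline."""
    return float(border.line.distance(Point(point)))


def distance_matrix(
    points: Sequence[tuple[float, float]], traps: Sequence[TrapRecord]
) -> np.ndarray:
    """Point-to-trap Euclidean distance matrix, shape (n_points, n_traps)."""
    if len(points) == 0 or len(traps) == 0:
        raise ValueError("points and traps must be nonempty")
    p = np.asarray(points, dtype=float)
    t = np.asarray([(tr.x, tr.y) for tr in traps], dtype=float)
    return cdist(p, t)


CatchIndexVariant = Literal["displayed", "text"]


def catch_index(
    point_index: int,
    traps: Sequence[TrapRecord],
    distances: np.ndarray,
    variant: CatchIndexVariant = "displayed",
) -> float:
    """Distance-weighted trap-catch index for one assessment point.

    Two formulations of this index circulate — a plain inverse-square
    weighted sum and a root-sum-of-squares of the catch/distance ratios —
    so both are implemented:

    - ``displayed``: sum_x H_x / d_xi^2 (default)
    - ``text``: sqrt(sum_x (H_x / d_xi)^2)

    Both are 1-homogeneous in the catches H and strictly decreasing in every
    distance; both weight high catches at short range most heavily.
    """
    d = np.asarray(distances[point_index], dtype=float)
    if np.any(d <= 0):
        raise ValueError("catch index undefined at zero trap distance")
    h = np.array([t.total_catch for t in traps], dtype=float)
    if variant == "displayed":
        return float(np.sum(h / d**2))
    if variant == "text":
        return float(math.sqrt(np.sum((h / d) ** 2)))
    raise ValueError(f"unknown catch-index variant: {variant!r}")


def lonlat_to_local_xy(
    lonlat: Sequence[tuple[float, float]],
    origin: tuple[float, float] | None = None,
) -> np.ndarray:
    """Project (lon, lat) degrees to local planar meters.

    Equirectangular about the centroid (or a given origin): adequate below a
    few km of extent, which covers any orchard block.
    """
    a = np.asarray(lonlat, dtype=float)
    if origin is None:
        origin = tuple(a.mean(axis=0))
    lon0, lat0 = origin
    x = np.radians(a[:, 0] - lon0) * math.cos(math.radians(lat0)) * EARTH_RADIUS_M
    y = np.radians(a[:, 1] - lat0) * EARTH_RADIUS_M
    return np.column_stack([x, y])


# --- GeoJSON / CSV I/O -----------------------------------------------------

def border_from_geojson(path: str) -> BorderPolyline:
    """Read the first LineString feature of a GeoJSON file as the border."""
    with open(path) as fh:
        gj = json.load(fh)
    for feat in gj.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") == "LineString":
            return BorderPolyline(tuple(map(tuple, geom["coordinates"])))
    raise ValueError(f"no LineString feature in {path}")


def traps_from_geojson(path: str) -> list[tuple[str, float, float]]:
    """Read Point features (id, x, y) from a GeoJSON file."""
    with open(path) as fh:
        gj = json.load(fh)
    out = []
    for feat in gj.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") == "Point":
            x, y = geom["coordinates"]
            out.append((str(feat.get("properties", {}).get("id", len(out))), x, y))
    if not out:
        raise ValueError(f"no Point features in {path}")
    return out


def geojson_feature_collection(
    border: BorderPolyline, traps: Iterable[TrapRecord]
) -> dict:
    """GeoJSON FeatureCollection of the border line and trap points."""
    features: list[dict] = [
        {
            "type": "Feature",
            "properties": {"role": "border"},
            "geometry": {
                "type": "LineString",
                "coordinates": [list(v) for v in border.vertices],
            },
        }
    ]
    for t in traps:
        features.append(
            {
                "type": "Feature",
                "properties": {"role": "trap", "id": t.id},
                "geometry": {"type": "Point", "coordinates": [t.x, t.y]},
            }
        )
    return {"type": "FeatureCollection", "features": features}
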