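"""Planar geometry for river-barrier analyses.

Rivers are simple polylines in a projected CRS (metres). A dispersal is the
straight segment between two individuals' spatial centers. A river counts as
*crossed* when that segment intersects the river's polyline an odd number of
times (endpoints on opposite banks); an even number of intersections means the
track returned to its starting bank, so the river was not crossed in the sense
that matters for a barrier analysis.

Directions are classified against a reference line "orthogonal to the rivers":
angles are folded to [0, 90] degrees between undirected lines, and angles
<= 45 degrees are class D1 (orthogonal to rivers), > 45 degrees D2 (parallel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, Point

__all__ = [
    "RiverSet",
    "segment_polyline_intersections",
    "rivers_crossed",
    "rivers_crossed_batch",
    "crossed_any_batch",
    "band_index",
    "dispersal_distance_km",
    "dispersal_angle_deg",
    "classify_direction",
]

#: nudge (metres) applied to an endpoint lying exactly on a river polyline,
#: toward the segment's other endpoint, before counting intersections.
ENDPOINT_EPS = 1e-3
#: tolerance (metres) for deciding that a point lies on a polyline.
ON_LINE_TOL = 1e-9


@dataclass
class RiverSet:
    """Ordered, named river polylines plus the dispersal reference azimuth.

    Rivers are ordered south to north. ``reference_azimuth_deg`` is the
    compass azimuth (degrees clockwise from grid north) of the reference
    line orthogonal to the mean river course.
    """

    names: list[str]
    lines: list[LineString]
    reference_azimuth_deg: float
    extent: tuple[float, float, float, float] | None = None  # xmin, ymin, xmax, ymax
    _prepared: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lines):
            raise ValueError("names and lines must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("river names must be unique")
        for name, line in zip(self.names, self.lines):
            if len(line.coords) < 2:
                raise ValueError(f"river {name!r}: polyline needs >= 2 vertices")
            if not line.is_simple:
                raise ValueError(f"river {name!r}: polyline is self-intersecting")

    def __len__(self) -> int:
        return len(self.lines)

    def __iter__(self):
        return iter(zip(self.names, self.lines))


def _as_xy(p) -> tuple[float, float]:
    return float(p[0]), float(p[1])


def _nudged_endpoints(p1, p2, line: LineString) -> tuple[tuple, tuple]:
    """Resolve the measure-zero case of an endpoint lying exactly on the line.

    The offending endpoint is moved ENDPOINT_EPS toward the other endpoint,
    which is deterministic and keeps the segment direction unchanged.
    """
    x1, y1 = _as_xy(p1)
    x2, y2 = _as_xy(p2)
    dx, dy = x2 - x1, y2 - y1
    norm = math.hypot(dx, dy)
    ux, uy = dx / norm, dy / norm
    if line.distance(Point(x1, y1)) <= ON_LINE_TOL:
        x1, y1 = x1 + ENDPOINT_EPS * ux, y1 + ENDPOINT_EPS * uy
    if line.distance(Point(x2, y2)) <= ON_LINE_TOL:
        x2, y2 = x2 - ENDPOINT_EPS * ux, y2 - ENDPOINT_EPS * uy
    return (x1, y1), (x2, y2)


def _count_point_intersections(geom) -> int:
    """Number of 0-dimensional pieces of an intersection geometry.

    Collinear-overlap (1-dimensional) pieces are ignored: sliding along a
    river is not a crossing.
    """
    if geom.is_empty:
        return 0
    if geom.geom_type == "Point":
        return 1
    if geom.geom_type == "MultiPoint":
        return len(geom.geoms)
    if geom.geom_type in ("LineString", "MultiLineString"):
        return 0
    if geom.geom_type == "GeometryCollection":
        return sum(_count_point_intersections(g) for g in geom.geoms)
    raise TypeError(f"unexpected intersection geometry {geom.geom_type}")


def segment_polyline_intersections(p1, p2, line: LineString) -> int:
    """Count proper intersection points of the segment p1-p2 with a polyline.

    Endpoints lying exactly on the polyline are nudged toward the opposite
    endpoint before counting; collinear overlap contributes no intersections.

    Raises ValueError for a degenerate (zero-length) segment.
    """
    if _as_xy(p1) == _as_xy(p2):
        raise ValueError("segment endpoints coincide; crossing count undefined")
    q1, q2 = _nudged_endpoints(p1, p2, line)
    return _count_point_intersections(LineString([q1, q2]).intersection(line))


def rivers_crossed(p1, p2, rivers: RiverSet) -> int:
    """Number of rivers crossed by the straight segment p1-p2.

    A river is crossed iff the segment intersects its polyline an odd number
    of times (odd parity = endpoints on opposite banks).
    """
    return sum(
        segment_polyline_intersections(p1, p2, line) % 2 for line in rivers.lines
    )


def rivers_crossed_batch(starts: np.ndarray, ends: np.ndarray, rivers: RiverSet) -> np.ndarray:
    """Vectorized ``rivers_crossed`` for arrays of segments.

    ``starts`` and ``ends`` are (n, 2) arrays of metres. Returns an (n,)
    integer array of rivers crossed per segment. Degenerate endpoint-on-river
    cases fall back to the scalar path.
    """
    starts = np.asarray(starts, dtype=float)
    ends = np.asarray(ends, dtype=float)
    if starts.shape != ends.shape or starts.ndim != 2 or starts.shape[1] != 2:
        raise ValueError("starts and ends must be matching (n, 2) arrays")
    n = len(starts)
    if np.any(np.all(starts == ends, axis=1)):
        raise ValueError("zero-length segment in batch")
    coords = np.stack([starts, ends], axis=1)  # (n, 2, 2)
    segs = shapely.linestrings(coords)
    crossed = np.zeros(n, dtype=np.int64)
    for line in rivers.lines:
        inter = shapely.intersection(segs, np.full(n, line, dtype=object))
        type_id = shapely.get_type_id(inter)
        counts = np.zeros(n, dtype=np.int64)
        counts[type_id == 0] = 1  # Point
        is_multi = type_id == 4  # MultiPoint
        counts[is_multi] = shapely.get_num_geometries(inter[is_multi])
        # rare mixed/linear results (grazing, collinear overlap): exact scalar path
        odd = (type_id > 0) & ~is_multi & (type_id != -1) & (type_id != 1) & (type_id != 5)
        for i in np.nonzero(odd)[0]:
            counts[i] = segment_polyline_intersections(starts[i], ends[i], line)
        crossed += counts % 2
    return crossed


def crossed_any_batch(starts: np.ndarray, ends: np.ndarray, rivers: RiverSet) -> np.ndarray:
    """Boolean array: did each segment cross at least one river?"""
    if len(rivers) == 0:
        return np.zeros(len(np.atleast_2d(starts)), dtype=bool)
    return rivers_crossed_batch(starts, ends, rivers) >= 1


def band_index(point, rivers: RiverSet) -> int:
    """Index (0-based, south to north) of the inter-river band containing a point.

    Computed by crossing parity along a ray from far south of all rivers to
    the point, so it is consistent with ``rivers_crossed`` for any simple
    river spanning the extent.
    """
    x, y = _as_xy(point)
    ymin = min(line.bounds[1] for line in rivers.lines) if len(rivers) else 0.0
    origin = (x, ymin - 1.0e4)
    if len(rivers) == 0:
        return 0
    return rivers_crossed(origin, (x, y), rivers)


def dispersal_distance_km(p1, p2) -> float:
    """Euclidean distance between two points in metres, reported in km."""
    x1, y1 = _as_xy(p1)
    x2, y2 = _as_xy(p2)
    return math.hypot(x2 - x1, y2 - y1) / 1000.0


def azimuth_unit_vector(azimuth_deg: float) -> tuple[float, float]:
    """Unit vector of a compass azimuth (clockwise from grid north = +y)."""
    a = math.radians(azimuth_deg)
    return math.sin(a), math.cos(a)


def dispersal_angle_deg(p1, p2, reference_azimuth_deg: float) -> float:
    """Acute angle (degrees, in [0, 90]) between the undirected line p1-p2
    and the undirected reference line at the given azimuth."""
    x1, y1 = _as_xy(p1)
    x2, y2 = _as_xy(p2)
    dx, dy = x2 - x1, y2 - y1
    norm = math.hypot(dx, dy)
    if norm == 0.0:
        raise ValueError("angle of a zero-length displacement is undefined")
    ux, uy = azimuth_unit_vector(reference_azimuth_deg)
    cosang = abs(dx * ux + dy * uy) / norm
    return math.degrees(math.acos(min(1.0, cosang)))


def classify_direction(angle_deg: float) -> str:
    """D1 ("orthogonal to rivers") iff angle <= 45 degrees, else D2."""
    if not 0.0 <= angle_deg <= 90.0:
        raise ValueError("angle must be folded to [0, 90] degrees")
    return "D1" if angle_deg <= 45.0 else "D2"
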