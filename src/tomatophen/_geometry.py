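"""Shared planar-geometry helpers (pixel coordinates, x right / y down)."""

from __future__ import annotations

import math

import numpy as np
from shapely.geometry import LineString, MultiPoint, Point, Polygon


def ellipse_ring(
    cx: float, cy: float, rx: float, ry: float, n: int = 360,
    t0: float = 0.0, t1: float = 2.0 * math.pi, rotation: float = 0.0,
) -> np.ndarray:
    """Vertices of an (arc of an) ellipse as an (n, 2) xy array.

    ``t`` is the parametric angle; with y pointing down, t in [0, pi] traces
    the lower half from (cx+rx, cy) to (cx-rx, cy).
    """
    t = np.linspace(t0, t1, n, endpoint=abs((t1 - t0) - 2 * math.pi) > 1e-12)
    x = rx * np.cos(t)
    y = ry * np.sin(t)
    if rotation:
        c, s = math.cos(rotation), math.sin(rotation)
        x, y = c * x - s * y, s * x + c * y
    return np.column_stack([cx + x, cy + y])


def shoelace_area(xy: np.ndarray) -> float:
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def ensure_positive_orientation(xy: np.ndarray) -> np.ndarray:
    """Reverse the ring if its shoelace area is negative (fixes a traversal sign)."""
    return xy if shoelace_area(xy) >= 0 else xy[::-1].copy()


def perimeter(xy: np.ndarray, closed: bool = True) -> float:
    pts = np.vstack([xy, xy[:1]]) if closed else xy
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def point_line_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Perpendicular distance from p to the infinite line through a and b."""
    ab = b - a
    n = np.linalg.norm(ab)
    if n < 1e-12:
        return float(np.linalg.norm(p - a))
    ap = p - a
    cross_z = ab[0] * ap[1] - ab[1] * ap[0]
    return float(abs(cross_z) / n)


def min_area_rect(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotated minimum-area rectangle of a point set.

    Returns ``(lengths, directions)``: two side lengths and the corresponding
    unit direction vectors, unordered.
    """
    rect = MultiPoint([tuple(p) for p in np.asarray(points, float)]).minimum_rotated_rectangle
    coords = np.asarray(rect.exterior.coords) if rect.geom_type == "Polygon" else None
    if coords is None or len(coords) < 5:
        raise ValueError("degenerate point set for minimum-area rectangle")
    e1 = coords[1] - coords[0]
    e2 = coords[2] - coords[1]
    l1, l2 = np.linalg.norm(e1), np.linalg.norm(e2)
    d1 = e1 / l1 if l1 > 0 else np.array([1.0, 0.0])
    d2 = e2 / l2 if l2 > 0 else np.array([0.0, 1.0])
    return np.array([l1, l2]), np.vstack([d1, d2])


def _intersection_params(
    origin: np.ndarray, direction: np.ndarray, geom, ray: LineString
) -> list[float]:
    inter = ray.intersection(geom)
    if inter.is_empty:
        return []
    pts: list[tuple[float, float]] = []
    stack = [inter]
    while stack:
        g = stack.pop()
        if g.geom_type == "Point":
            pts.append((g.x, g.y))
        elif g.geom_type in ("MultiPoint", "GeometryCollection", "MultiLineString"):
            stack.extend(list(g.geoms))
        elif g.geom_type == "LineString":
            pts.extend(list(g.coords))
    return [float(np.dot(np.asarray(p) - origin, direction)) for p in pts]


def ray_radial_gap(
    section: Polygon,
    locule: Polygon,
    origin: tuple[float, float],
    target: tuple[float, float],
) -> float | None:
    """Radial flesh gap along the ray ``origin -> target`` (the pericarp ray).

    Casts a ray from the section centre through the locule centre, takes the
    farthest crossing of the locule boundary and the farthest crossing of the
    section boundary beyond it, and returns the distance between the two
    (pixels). Returns None when the ray is undefined (coincident centres) or
    fails to cross both boundaries in order.
    """
    o = np.asarray(origin, dtype=float)
    t = np.asarray(target, dtype=float)
    d = t - o
    norm = np.linalg.norm(d)
    if norm < 1e-9:
        return None
    d = d / norm
    minx, miny, maxx, maxy = section.bounds
    reach = 4.0 * max(maxx - minx, maxy - miny, 1.0)
    ray = LineString([tuple(o), tuple(o + d * reach)])
    t_loc = _intersection_params(o, d, locule.exterior, ray)
    t_sec = _intersection_params(o, d, section.exterior, ray)
    if not t_loc or not t_sec:
        return None
    outer_loc = max(t_loc)
    outer_sec = max(t_sec)
    if outer_sec <= outer_loc:
        return None
    return float(outer_sec - outer_loc)


def polygon_of(xy: np.ndarray) -> Polygon:
    """Shapely polygon from an (n, 2) xy ring, repaired if self-touching."""
    poly = Polygon(np.asarray(xy, dtype=float))
    if not poly.is_valid:
        poly = poly.buffer(0)
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda g: g.area)
    return poly


def farthest_point_index(points: np.ndarray, ref: np.ndarray) -> int:
    return int(np.argmax(np.linalg.norm(points - ref[None, :], axis=1)))
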