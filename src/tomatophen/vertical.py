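"""Vertical-cut phenotyping: diameters, navel/top landmarks, angles.

The measurement chain follows the landmark procedure for a vertical fruit
section:

1. extract the fruit contour;
2. simplify it with the Douglas-Peucker algorithm and label each retained
   vertex convex or concave from its turn direction;
3. the navel point is the concave vertex with the largest perpendicular
   distance to the chord through its two adjacent convex vertices;
4. when several concave candidates score close to the maximum, the tie is
   broken by the lowest mean saturation of the image region between the
   candidate and the contour centroid (the tissue near the calyx is paler
   than the rest of the section);
5. the top point is the contour point farthest from the navel;
6. top and navel angles are the vertex angles between the rays to the
   adjacent convex landmarks;
7. the shape index is vertical over horizontal diameter and the top/navel
   ratio is top angle over navel angle.

Diameters come from the rotated minimum-area rectangle enclosing the
contour; the rectangle side best aligned with the navel-to-top axis is the
vertical diameter, so the assignment survives in-plane rotation of the
scene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import approximate_polygon as _dp_approximate

from ._geometry import (
    ensure_positive_orientation,
    farthest_point_index,
    min_area_rect,
    perimeter,
    point_line_distance,
)
from .errors import CalibrationError, DegenerateContourError, NoNavelError
from .io import PixelScale
from .isolation import FruitInstance, hsv_channels

__all__ = [
    "LabeledPolygon",
    "LandmarkSet",
    "VerticalPhenotype",
    "approximate_polygon",
    "find_navel_point",
    "find_top_point",
    "vertex_angle",
    "measure_vertical_phenotype",
]

#: Douglas-Peucker tolerance as a fraction of the contour perimeter. The
#: simplified polygon stays within tolerance of the contour, so retained
#: corner vertices can wander by up to that amount along the outline; angle
#: errors scale with tolerance over the landmark lever arm (tens of pixels).
#: 0.005 of the perimeter keeps that error near one degree while remaining an
#: order of magnitude above marching-squares rasterization noise. The
#: sensitivity to this choice is discussed in the methods documentation.
DEFAULT_EPSILON_FRAC = 0.005

#: Concave candidates scoring at least this fraction of the best chord
#: distance trigger the saturation disambiguation step.
TIE_BAND = 0.8


@dataclass
class LabeledPolygon:
    """Douglas-Peucker simplification of a closed contour.

    ``vertices`` are a subset of the contour points (order preserved,
    counter-clockwise after normalization); ``convex[i]`` labels the turn
    at ``vertices[i]``; ``contour_index[i]`` maps back into ``contour``.
    """

    vertices: np.ndarray
    convex: np.ndarray
    contour: np.ndarray
    contour_index: np.ndarray

    def __len__(self) -> int:
        return len(self.vertices)


def approximate_polygon(
    contour: np.ndarray, epsilon_frac: float = DEFAULT_EPSILON_FRAC
) -> LabeledPolygon:
    """Simplify a closed contour and label vertices convex/concave.

    Tolerance is ``epsilon_frac`` of the contour perimeter. The contour is
    normalized to positive (counter-clockwise) orientation first so that a
    positive turn cross-product always means convex.
    """
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or len(contour) < 8:
        raise DegenerateContourError(
            f"contour must have >= 8 points, got {contour.shape}"
        )
    if not (0.0 < epsilon_frac < 0.2):
        raise ValueError("epsilon_frac must be in (0, 0.2)")
    contour = ensure_positive_orientation(contour)
    tol = epsilon_frac * perimeter(contour)
    closed = np.vstack([contour, contour[:1]])
    simplified = _dp_approximate(closed, tolerance=tol)
    if len(simplified) > 1 and np.allclose(simplified[0], simplified[-1]):
        simplified = simplified[:-1]
    if len(simplified) < 3:
        raise DegenerateContourError("contour collapsed under simplification")

    # map simplified vertices back to contour indices (order-preserving walk)
    idx = np.empty(len(simplified), dtype=int)
    ptr = 0
    for i, v in enumerate(simplified):
        while ptr < len(contour) and not np.allclose(contour[ptr], v):
            ptr += 1
        if ptr >= len(contour):  # defensive: nearest match fallback
            ptr = int(np.argmin(np.linalg.norm(contour - v[None, :], axis=1)))
        idx[i] = ptr

    n = len(simplified)
    convex = np.empty(n, dtype=bool)
    for i in range(n):
        p0 = simplified[(i - 1) % n]
        p1 = simplified[i]
        p2 = simplified[(i + 1) % n]
        cross = (p1[0] - p0[0]) * (p2[1] - p1[1]) - (p1[1] - p0[1]) * (p2[0] - p1[0])
        convex[i] = cross >= 0
    return LabeledPolygon(vertices=simplified, convex=convex,
                          contour=contour, contour_index=idx)


def _adjacent_convex(poly: LabeledPolygon, i: int) -> tuple[np.ndarray, np.ndarray]:
    """Nearest convex vertices before and after ring position ``i``."""
    n = len(poly)
    left = right = None
    for step in range(1, n):
        j = (i - step) % n
        if poly.convex[j]:
            left = poly.vertices[j]
            break
    for step in range(1, n):
        j = (i + step) % n
        if poly.convex[j]:
            right = poly.vertices[j]
            break
    if left is None or right is None:
        raise NoNavelError("polygon has no convex vertices")
    return left, right


def _adjacent_convex_of_contour_point(
    poly: LabeledPolygon, contour_idx: int, exclude_radius_px: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest convex polygon vertices on either side of a raw contour position.

    Vertices within ``exclude_radius_px`` of the query point are skipped: the
    query (e.g. the farthest-point fruit top) may sit a pixel away from the
    retained apex vertex, which must not become its own neighbour.
    """
    query = poly.contour[contour_idx]
    order = np.sort(poly.contour_index)
    rank = {ci: k for k, ci in enumerate(poly.contour_index)}
    pos = np.searchsorted(order, contour_idx)
    n = len(poly)

    def vertex_at(slot: int) -> int:
        return rank[order[slot % len(order)]]

    def is_query(j: int) -> bool:
        return np.linalg.norm(poly.vertices[j] - query) <= exclude_radius_px

    right = None
    for step in range(0, n):
        j = vertex_at(pos + step)
        if is_query(j):
            continue
        if poly.convex[j]:
            right = poly.vertices[j]
            break
    left = None
    for step in range(1, n + 1):
        j = vertex_at(pos - step)
        if is_query(j):
            continue
        if poly.convex[j]:
            left = poly.vertices[j]
            break
    if left is None or right is None:
        raise NoNavelError("polygon has no convex vertices")
    return left, right


def find_navel_point(
    poly: LabeledPolygon,
    hsv_image: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    tie_band: float = TIE_BAND,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Locate the navel point and its adjacent convex pair.

    Primary criterion: the concave vertex with the largest perpendicular
    distance to the chord through its adjacent convex vertices. When two or
    more candidates fall within ``tie_band`` of the maximum, the candidate
    whose crop toward the contour centroid has the lowest mean saturation
    wins (requires ``hsv_image``, the saturation channel scaled 0-255, and
    optionally the fruit ``mask`` to restrict the crop).

    Raises :class:`NoNavelError` when the polygon has no concave vertex.
    """
    concave_idx = np.nonzero(~poly.convex)[0]
    if len(concave_idx) == 0:
        raise NoNavelError("no concave vertex on the simplified contour")
    scored = []
    for i in concave_idx:
        left, right = _adjacent_convex(poly, int(i))
        dist = point_line_distance(poly.vertices[i], left, right)
        scored.append((int(i), dist, left, right))
    best = max(s[1] for s in scored)
    candidates = [s for s in scored if s[1] >= tie_band * best]
    if len(candidates) > 1 and hsv_image is not None:
        centroid = poly.contour.mean(axis=0)
        sat = hsv_image[..., 1] if hsv_image.ndim == 3 else hsv_image

        def crop_saturation(pt: np.ndarray) -> float:
            x0, x1 = sorted((pt[0], centroid[0]))
            y0, y1 = sorted((pt[1], centroid[1]))
            r0, r1 = int(max(0, math.floor(y0))), int(math.ceil(y1)) + 1
            c0, c1 = int(max(0, math.floor(x0))), int(math.ceil(x1)) + 1
            window = sat[r0:r1, c0:c1]
            if mask is not None:
                sub = mask[r0:r1, c0:c1]
                if sub.any():
                    return float(window[sub].mean())
            return float(window.mean()) if window.size else float("inf")

        winner = min(candidates, key=lambda s: crop_saturation(poly.vertices[s[0]]))
    else:
        winner = max(candidates, key=lambda s: s[1])
    i, _, left, right = winner
    return poly.vertices[i], (left, right)


def find_top_point(
    poly: LabeledPolygon, navel_point: np.ndarray
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Fruit top = contour point farthest from the navel, with its adjacent
    convex polygon vertices on either side along the contour."""
    navel_point = np.asarray(navel_point, dtype=float)
    top_idx = farthest_point_index(poly.contour, navel_point)
    top = poly.contour[top_idx]
    left, right = _adjacent_convex_of_contour_point(poly, top_idx)
    return top, (left, right)


def vertex_angle(vertex, left_pt, right_pt) -> float:
    """Unsigned angle (degrees, (0, 180]) between rays vertex->left and
    vertex->right."""
    v = np.asarray(vertex, dtype=float)
    u = np.asarray(left_pt, dtype=float) - v
    w = np.asarray(right_pt, dtype=float) - v
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu < 1e-9 or nw < 1e-9:
        raise DegenerateContourError("coincident points give an undefined angle")
    cosang = np.clip(np.dot(u, w) / (nu * nw), -1.0, 1.0)
    return float(math.degrees(math.acos(cosang)))


@dataclass
class LandmarkSet:
    navel_point: tuple[float, float]
    top_point: tuple[float, float]
    navel_left_convex: tuple[float, float]
    navel_right_convex: tuple[float, float]
    top_left_convex: tuple[float, float]
    top_right_convex: tuple[float, float]


@dataclass
class VerticalPhenotype:
    fruit_id: int
    horizontal_diameter_cm: float
    vertical_diameter_cm: float
    shape_index: float
    top_angle_deg: float
    navel_angle_deg: float
    top_navel_ratio: float
    landmarks: LandmarkSet
    warnings: list[str] = field(default_factory=list)
    image_id: str = ""

    def to_row(self) -> dict:
        return {
            "image_id": self.image_id,
            "fruit_id": self.fruit_id,
            "horizontal_diameter_cm": self.horizontal_diameter_cm,
            "vertical_diameter_cm": self.vertical_diameter_cm,
            "shape_index": self.shape_index,
            "top_angle_deg": self.top_angle_deg,
            "navel_angle_deg": self.navel_angle_deg,
            "top_navel_ratio": self.top_navel_ratio,
            "n_warnings": len(self.warnings),
        }


def measure_vertical_phenotype(
    image: np.ndarray,
    instance: FruitInstance,
    scale: PixelScale | None,
    *,
    epsilon_frac: float = DEFAULT_EPSILON_FRAC,
    tie_band: float = TIE_BAND,
) -> VerticalPhenotype:
    """Measure all vertical-cut indicators for one fruit instance.

    Requires an explicit :class:`PixelScale`; raises
    :class:`CalibrationError` otherwise. When no concave navel candidate
    exists the bottom-most contour point is used as a fallback navel and the
    phenotype carries a ``"no-navel-fallback"`` warning.
    """
    if scale is None:
        raise CalibrationError("a PixelScale is required for vertical measurement")
    warnings: list[str] = []
    poly = approximate_polygon(instance.contour, epsilon_frac)
    h, s, v = hsv_channels(image)
    hsv = np.dstack([h, s, v])
    try:
        navel, (nl, nr) = find_navel_point(poly, hsv, instance.mask, tie_band)
    except NoNavelError:
        warnings.append("no-navel-fallback")
        bottom_idx = int(np.argmax(poly.contour[:, 1]))
        navel = poly.contour[bottom_idx]
        nl, nr = _adjacent_convex_of_contour_point(poly, bottom_idx)
    top, (tl, tr) = find_top_point(poly, navel)

    navel_angle = vertex_angle(navel, nl, nr)
    top_angle = vertex_angle(top, tl, tr)

    lengths, dirs = min_area_rect(poly.contour)
    axis = np.asarray(top, float) - np.asarray(navel, float)
    axis_norm = np.linalg.norm(axis)
    if axis_norm < 1e-9:
        raise DegenerateContourError("navel and top coincide")
    axis = axis / axis_norm
    alignment = np.abs(dirs @ axis)
    vertical_px = float(lengths[np.argmax(alignment)])
    horizontal_px = float(lengths[np.argmin(alignment)])

    vd = scale.px_to_cm(vertical_px)
    hd = scale.px_to_cm(horizontal_px)
    landmarks = LandmarkSet(
        navel_point=tuple(np.asarray(navel, float)),
        top_point=tuple(np.asarray(top, float)),
        navel_left_convex=tuple(np.asarray(nl, float)),
        navel_right_convex=tuple(np.asarray(nr, float)),
        top_left_convex=tuple(np.asarray(tl, float)),
        top_right_convex=tuple(np.asarray(tr, float)),
    )
    return VerticalPhenotype(
        fruit_id=instance.fruit_id,
        horizontal_diameter_cm=hd,
        vertical_diameter_cm=vd,
        shape_index=vd / hd,
        top_angle_deg=top_angle,
        navel_angle_deg=navel_angle,
        top_navel_ratio=top_angle / navel_angle,
        landmarks=landmarks,
        warnings=warnings,
    )
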