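"""Synthetic fruit scenes with analytic ground truth.

Every downstream stage of the pipeline (calibration, isolation, vertical-cut
geometry, locule analysis, evaluation) is testable without a single real
photograph: this module renders the four scene types of the acquisition
protocol — ruler card, intact fruits, vertical cuts, horizontal cuts — from
explicit geometric specifications, and reports the true value of every
phenotype the pipeline measures, computed analytically from the same
geometry that is rasterized.

Renderer conventions
--------------------
* No anti-aliasing: mask-defining shapes are rasterized with hard edges so
  ground-truth areas are exact pixel memberships, not renderer-dependent.
* Vertical-cut fruits are built from a lower half-ellipse "belly", a conical
  top whose apex angle is the ground-truth top angle, and an isosceles wedge
  notch carved at the bottom apex whose apex angle is the ground-truth navel
  angle. The cone construction keeps the fruit top point the farthest
  contour point from the navel and makes its adjacent convex landmarks the
  cone base corners, so both angles are analytically exact.
* A low-saturation (whitish-pink) band is painted inside the navel notch to
  emulate the pale tissue near the calyx on a real vertical section; its
  saturation still clears the foreground thresholds so it never punches a
  hole in the fruit mask.
* Horizontal-cut locules are polygons rasterized with the same routine used
  to rasterize their annotations, so annotation/raster round-trips are
  exact up to marching-squares tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from shapely.geometry import Polygon
from shapely.ops import unary_union
from skimage.draw import polygon as draw_polygon

from ._geometry import ellipse_ring, polygon_of, ray_radial_gap
from .errors import InvalidSpecError
from .io import AnnotationSet

__all__ = [
    "LoculeSpec",
    "FruitSpec",
    "SyntheticSceneSpec",
    "GroundTruthRecord",
    "render_ruler_card",
    "render_scene",
    "make_vertical_fruit",
    "make_horizontal_fruit",
    "concentric_locule_fruit",
    "make_intact_scene",
    "make_vertical_scene",
    "make_horizontal_scene",
    "make_vertical_cohort",
    "make_horizontal_cohort",
    "make_augmentation_sources",
    "scale_spec",
]

SceneKind = Literal["ruler", "intact", "vertical", "horizontal"]

#: Default flesh / locule / band colours. All hues sit inside the 0-180 degree
#: acceptance window of the built-in presets; the band keeps S above the
#: pure-colour saturation floor while being clearly paler than fruit flesh.
FLESH_RGB = (215, 70, 60)
LOCULE_RGB = (120, 45, 40)
BAND_RGB = (210, 100, 100)

_RIGHT_ANGLE_EPS = 1e-9


@dataclass
class LoculeSpec:
    """One locule: an absolute-coordinate polygon plus its fill colour."""

    polygon: np.ndarray  # (n, 2) float xy
    fill_color: tuple[int, int, int] = LOCULE_RGB

    def shapely(self) -> Polygon:
        return polygon_of(self.polygon)


@dataclass
class FruitSpec:
    """Geometry of one fruit (or cut section) in a synthetic scene.

    ``navel_notch_angle`` / ``top_protrusion_angle`` (degrees, (0, 180])
    apply to vertical scenes; ``locules`` and ``pericarp_thickness_px`` to
    horizontal scenes. ``speckle`` is the half-amplitude of uniform
    zero-mean integer colour noise applied inside the fruit.
    """

    center: tuple[float, float]
    horizontal_radius: float
    vertical_radius: float
    fill_color: tuple[int, int, int] = FLESH_RGB
    navel_notch_angle: float | None = None
    top_protrusion_angle: float | None = None
    notch_depth_frac: float = 0.2
    paint_navel_band: bool = True
    band_color: tuple[int, int, int] = BAND_RGB
    locules: list[LoculeSpec] = field(default_factory=list)
    pericarp_thickness_px: float | None = None
    slit_width_px: int = 0
    speckle: int = 0

    def __post_init__(self) -> None:
        if self.horizontal_radius <= 0 or self.vertical_radius <= 0:
            raise InvalidSpecError("fruit radii must be positive")
        for name, ang in (
            ("navel_notch_angle", self.navel_notch_angle),
            ("top_protrusion_angle", self.top_protrusion_angle),
        ):
            if ang is not None and not (0.0 < ang <= 180.0):
                raise InvalidSpecError(f"{name} must be in (0, 180], got {ang}")
        if not (0.0 < self.notch_depth_frac < 1.0):
            raise InvalidSpecError("notch_depth_frac must be in (0, 1)")

    # -- geometry ----------------------------------------------------------

    def ellipse_polygon(self) -> Polygon:
        cx, cy = self.center
        return polygon_of(ellipse_ring(cx, cy, self.horizontal_radius,
                                       self.vertical_radius, 720))

    def section_polygon(self) -> Polygon:
        cx, cy = self.center
        r = self.horizontal_radius
        return polygon_of(ellipse_ring(cx, cy, r, r, 720))

    @property
    def top_apex(self) -> tuple[float, float]:
        cx, cy = self.center
        a, b = self.horizontal_radius, self.vertical_radius
        if self.top_protrusion_angle is None:
            return (cx, cy - b)
        half = math.radians(self.top_protrusion_angle) / 2.0
        h_top = a / max(math.tan(half), _RIGHT_ANGLE_EPS)
        return (cx, cy - h_top)

    @property
    def navel_apex(self) -> tuple[float, float] | None:
        if self.navel_notch_angle is None:
            return None
        cx, cy = self.center
        b = self.vertical_radius
        return (cx, cy + b - self.notch_depth_frac * b)

    def vertical_polygon(self) -> Polygon:
        cx, cy = self.center
        a, b = self.horizontal_radius, self.vertical_radius
        if self.top_protrusion_angle is None:
            ring = ellipse_ring(cx, cy, a, b, 720)
        else:
            belly = ellipse_ring(cx, cy, a, b, 361, t0=0.0, t1=math.pi)
            ring = np.vstack([belly, [self.top_apex]])
        poly = polygon_of(ring)
        if self.navel_notch_angle is not None:
            apex = np.asarray(self.navel_apex)
            half = math.radians(self.navel_notch_angle) / 2.0
            reach = 4.0 * b
            wedge = Polygon([
                tuple(apex),
                (apex[0] - reach * math.sin(half), apex[1] + reach * math.cos(half)),
                (apex[0] + reach * math.sin(half), apex[1] + reach * math.cos(half)),
            ])
            poly = poly.difference(wedge)
            if poly.geom_type == "MultiPolygon":
                poly = max(poly.geoms, key=lambda g: g.area)
        return poly

    def footprint(self, kind: SceneKind) -> Polygon:
        if kind == "vertical":
            return self.vertical_polygon()
        if kind == "horizontal":
            return self.section_polygon()
        return self.ellipse_polygon()

    def scaled(self, k: float) -> "FruitSpec":
        return replace(
            self,
            center=(self.center[0] * k, self.center[1] * k),
            horizontal_radius=self.horizontal_radius * k,
            vertical_radius=self.vertical_radius * k,
            locules=[LoculeSpec(l.polygon * k, l.fill_color) for l in self.locules],
            pericarp_thickness_px=(None if self.pericarp_thickness_px is None
                                   else self.pericarp_thickness_px * k),
            slit_width_px=int(round(self.slit_width_px * k)),
        )


@dataclass
class SyntheticSceneSpec:
    scene_kind: SceneKind
    image_size: tuple[int, int]  # (width, height)
    pixels_per_cm: float
    fruits: list[FruitSpec]
    background_color: tuple[int, int, int] = (255, 255, 255)

    def __post_init__(self) -> None:
        if self.pixels_per_cm <= 0:
            raise InvalidSpecError("pixels_per_cm must be positive")

    def scaled(self, k: float) -> "SyntheticSceneSpec":
        w, h = self.image_size
        return replace(
            self,
            image_size=(int(round(w * k)), int(round(h * k))),
            pixels_per_cm=self.pixels_per_cm * k,
            fruits=[f.scaled(k) for f in self.fruits],
        )


def scale_spec(spec: SyntheticSceneSpec, k: float) -> SyntheticSceneSpec:
    """Scale every pixel dimension of a scene by ``k`` (cm ground truth invariant)."""
    return spec.scaled(k)


@dataclass
class GroundTruthRecord:
    """True per-fruit values of every phenotype the pipeline measures."""

    fruit_id: int
    scene_kind: SceneKind
    pixels_per_cm: float | None = None
    mean_rgb: tuple[float, float, float] | None = None
    horizontal_diameter_cm: float | None = None
    vertical_diameter_cm: float | None = None
    shape_index: float | None = None
    top_angle_deg: float | None = None
    navel_angle_deg: float | None = None
    top_navel_ratio: float | None = None
    navel_point: tuple[float, float] | None = None
    top_point: tuple[float, float] | None = None
    locule_count: int | None = None
    locule_area_proportion: float | None = None
    pericarp_thickness_cm: float | None = None
    per_locule_thickness_cm: list[float] | None = None
    locule_polygons: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.locule_count is not None and self.locule_count < 0:
            raise InvalidSpecError("locule_count must be non-negative")
        if self.locule_area_proportion is not None and not (
            0.0 <= self.locule_area_proportion < 1.0
        ):
            raise InvalidSpecError("locule_area_proportion must be in [0, 1)")

    def to_row(self) -> dict:
        row: dict = {"fruit_id": self.fruit_id, "scene_kind": self.scene_kind}
        for name in (
            "mean_rgb", "horizontal_diameter_cm", "vertical_diameter_cm",
            "shape_index", "top_angle_deg", "navel_angle_deg", "top_navel_ratio",
            "locule_count", "locule_area_proportion", "pericarp_thickness_cm",
        ):
            val = getattr(self, name)
            if name == "mean_rgb" and val is not None:
                row["r"], row["g"], row["b"] = val
            elif val is not None:
                row[name] = val
        return row


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

def _fill_polygon(
    img: np.ndarray,
    poly: Polygon,
    color: tuple[int, int, int],
    rng: np.random.Generator | None = None,
    speckle: int = 0,
) -> np.ndarray:
    xy = np.asarray(poly.exterior.coords)
    rr, cc = draw_polygon(xy[:, 1], xy[:, 0], shape=img.shape[:2])
    if speckle > 0 and rng is not None:
        noise = rng.integers(-speckle, speckle + 1, size=(len(rr), 3))
        img[rr, cc] = np.clip(np.asarray(color, dtype=np.int64) + noise, 0, 255)
    else:
        img[rr, cc] = color
    mask = np.zeros(img.shape[:2], dtype=bool)
    mask[rr, cc] = True
    return mask


def _validate_scene(spec: SyntheticSceneSpec) -> None:
    w, h = spec.image_size
    polys = [f.footprint(spec.scene_kind) for f in spec.fruits]
    for f, poly in zip(spec.fruits, polys):
        minx, miny, maxx, maxy = poly.bounds
        if minx < 0.5 or miny < 0.5 or maxx > w - 1.5 or maxy > h - 1.5:
            raise InvalidSpecError(
                f"fruit footprint {poly.bounds} exceeds image bounds {(w, h)}"
            )
    for i in range(len(polys)):
        for j in range(i + 1, len(polys)):
            if polys[i].distance(polys[j]) < 2.0:
                raise InvalidSpecError(f"fruit footprints {i} and {j} overlap or touch")
    if spec.scene_kind == "horizontal":
        for i, f in enumerate(spec.fruits):
            section = f.section_polygon()
            flesh_v = max(f.fill_color)
            loc_polys = [l.shapely() for l in f.locules]
            for k, l in enumerate(f.locules):
                if not section.buffer(-1.0).contains(loc_polys[k]):
                    raise InvalidSpecError(
                        f"locule {k} of fruit {i} is not strictly inside the section"
                    )
                if flesh_v - max(l.fill_color) < 30:
                    raise InvalidSpecError(
                        f"locule {k} of fruit {i}: value gap to flesh below 30"
                    )
            for k in range(len(loc_polys)):
                for m in range(k + 1, len(loc_polys)):
                    if loc_polys[k].intersects(loc_polys[m]):
                        raise InvalidSpecError(
                            f"locules {k} and {m} of fruit {i} overlap"
                        )


def _vertical_ground_truth(f: FruitSpec, fid: int, ppcm: float) -> GroundTruthRecord:
    # Ground-truth diameters are the analytic twin of the indicator itself:
    # sides of the rotated minimum-area rectangle of the (unrasterized) fruit
    # polygon, assigned to vertical/horizontal by the navel-to-top axis.
    from ._geometry import min_area_rect

    poly = f.vertical_polygon()
    lengths, dirs = min_area_rect(np.asarray(poly.exterior.coords))
    navel = f.navel_apex
    if navel is not None:
        axis = np.asarray(f.top_apex) - np.asarray(navel)
        axis = axis / np.linalg.norm(axis)
    else:
        axis = np.array([0.0, -1.0])
    alignment = np.abs(dirs @ axis)
    vd = float(lengths[np.argmax(alignment)]) / ppcm
    hd = float(lengths[np.argmin(alignment)]) / ppcm
    top = f.top_protrusion_angle
    navel = f.navel_notch_angle
    return GroundTruthRecord(
        fruit_id=fid,
        scene_kind="vertical",
        pixels_per_cm=ppcm,
        horizontal_diameter_cm=hd,
        vertical_diameter_cm=vd,
        shape_index=vd / hd,
        top_angle_deg=top,
        navel_angle_deg=navel,
        top_navel_ratio=(top / navel if top is not None and navel is not None else None),
        navel_point=f.navel_apex,
        top_point=f.top_apex,
    )


def _horizontal_ground_truth(f: FruitSpec, fid: int, ppcm: float) -> GroundTruthRecord:
    section = f.section_polygon()
    loc_polys = [l.shapely() for l in f.locules]
    proportion = (
        unary_union(loc_polys).area / section.area if loc_polys else 0.0
    )
    center = (section.centroid.x, section.centroid.y)
    gaps = []
    for lp in loc_polys:
        gap = ray_radial_gap(section, lp, center, (lp.centroid.x, lp.centroid.y))
        if gap is not None:
            gaps.append(gap / ppcm)
    return GroundTruthRecord(
        fruit_id=fid,
        scene_kind="horizontal",
        pixels_per_cm=ppcm,
        locule_count=len(f.locules),
        locule_area_proportion=float(proportion),
        pericarp_thickness_cm=(float(np.mean(gaps)) if gaps else None),
        per_locule_thickness_cm=gaps or None,
        locule_polygons=[np.asarray(l.polygon, dtype=float) for l in f.locules],
    )


def render_scene(
    spec: SyntheticSceneSpec, seed: int = 0
) -> tuple[np.ndarray, list[GroundTruthRecord], AnnotationSet | None]:
    """Rasterize a scene; return (image, per-fruit ground truth, annotations).

    Deterministic for a fixed ``(spec, seed)`` — the seed drives only the
    speckle noise. The annotation set (horizontal scenes only) contains every
    locule polygon under the label ``"locule"``.
    """
    if spec.scene_kind == "ruler":
        raise InvalidSpecError("use render_ruler_card for ruler scenes")
    _validate_scene(spec)
    rng = np.random.default_rng(seed)
    w, h = spec.image_size
    img = np.full((h, w, 3), spec.background_color, dtype=np.uint8)
    records: list[GroundTruthRecord] = []
    shapes: list[tuple[str, np.ndarray]] = []

    for fid, f in enumerate(spec.fruits):
        if spec.scene_kind == "intact":
            _fill_polygon(img, f.ellipse_polygon(), f.fill_color, rng, f.speckle)
            records.append(GroundTruthRecord(
                fruit_id=fid,
                scene_kind="intact",
                pixels_per_cm=spec.pixels_per_cm,
                mean_rgb=tuple(float(c) for c in f.fill_color),
                horizontal_diameter_cm=2 * f.horizontal_radius / spec.pixels_per_cm,
                vertical_diameter_cm=2 * f.vertical_radius / spec.pixels_per_cm,
            ))
        elif spec.scene_kind == "vertical":
            mask = _fill_polygon(img, f.vertical_polygon(), f.fill_color, rng, f.speckle)
            if f.navel_notch_angle is not None and f.paint_navel_band:
                apex = f.navel_apex
                band_r = 0.6 * f.notch_depth_frac * f.vertical_radius + 4.0
                yy, xx = np.mgrid[0:h, 0:w]
                band = ((xx - apex[0]) ** 2 + (yy - apex[1]) ** 2 <= band_r ** 2) & mask
                img[band] = f.band_color
            records.append(_vertical_ground_truth(f, fid, spec.pixels_per_cm))
        elif spec.scene_kind == "horizontal":
            section_mask = _fill_polygon(img, f.section_polygon(), f.fill_color,
                                         rng, f.speckle)
            for l in f.locules:
                _fill_polygon(img, l.shapely(), l.fill_color, rng, f.speckle)
                shapes.append(("locule", np.asarray(l.polygon, dtype=float)))
            if f.slit_width_px > 0:
                cx = f.center[0]
                cols = np.abs(np.arange(w) - cx) <= f.slit_width_px / 2.0
                slit = section_mask & cols[None, :]
                img[slit] = spec.background_color
            records.append(_horizontal_ground_truth(f, fid, spec.pixels_per_cm))
        else:  # pragma: no cover - guarded by _validate_scene
            raise InvalidSpecError(f"unknown scene kind {spec.scene_kind!r}")

    annotations = None
    if spec.scene_kind == "horizontal":
        annotations = AnnotationSet(
            image_id="synthetic_horizontal",
            polygons=shapes,
            image_size=(h, w),
        )
    return img, records, annotations


def render_ruler_card(
    pitch_px: float, size: tuple[int, int] = (400, 400)
) -> tuple[np.ndarray, GroundTruthRecord]:
    """Render a black-white checkerboard ruler card.

    ``pitch_px`` is the rendered side of one (physically 1 cm x 1 cm) square;
    it must be at least 8 px for the squares to stay distinct, and the
    pattern must fit at least a 3 x 3 grid in the image.
    """
    if pitch_px < 8:
        raise InvalidSpecError(f"pitch_px must be >= 8, got {pitch_px}")
    w, h = size
    margin = 8
    k = int(min((min(w, h) - 2 * margin) // pitch_px, 10))
    if k < 3:
        raise InvalidSpecError("ruler card pattern does not fit in the image")
    img = np.full((h, w, 3), 255, dtype=np.uint8)
    for i in range(k):
        for j in range(k):
            if (i + j) % 2 == 0:
                r0 = int(round(margin + i * pitch_px))
                r1 = int(round(margin + (i + 1) * pitch_px))
                c0 = int(round(margin + j * pitch_px))
                c1 = int(round(margin + (j + 1) * pitch_px))
                img[r0:r1, c0:c1] = 0
    record = GroundTruthRecord(fruit_id=0, scene_kind="ruler", pixels_per_cm=pitch_px)
    return img, record


# --------------------------------------------------------------------------
# Fruit and scene builders
# --------------------------------------------------------------------------

def make_vertical_fruit(
    a_px: float,
    shape_ratio: float,
    navel_angle_deg: float,
    top_angle_deg: float,
    fill_color: tuple[int, int, int] = FLESH_RGB,
    *,
    notch_depth_frac: float = 0.4,
    dominance_margin_px: float = 12.0,
    speckle: int = 0,
) -> FruitSpec:
    """Vertical-cut fruit with exactly recoverable landmark angles.

    The default notch depth (0.4 of the belly half-height) gives the wedge
    sides a lever arm of several tens of pixels at realistic image scales,
    so that one-pixel rasterization jitter at the mouth corners perturbs the
    recovered navel angle by well under the landmark tolerance.

    ``a_px`` is the belly half-width; the belly half-height is the larger of
    ``shape_ratio * a_px`` and the minimum height for which the top apex is
    farther from the navel than the cone base corners by at least
    ``dominance_margin_px`` — the condition under which the farthest-point
    top detection provably lands on the apex.
    """
    half = math.radians(top_angle_deg) / 2.0
    h_top = a_px / max(math.tan(half), _RIGHT_ANGLE_EPS)
    c = h_top - dominance_margin_px
    if c <= 0:
        raise InvalidSpecError(
            f"top angle {top_angle_deg} deg too flat for dominance margin "
            f"{dominance_margin_px} px at half-width {a_px} px"
        )
    u_min = max((a_px * a_px - c * c) / (2.0 * c), 0.0)
    b_px = max(shape_ratio * a_px, u_min / (1.0 - notch_depth_frac) + 1.0)
    return FruitSpec(
        center=(0.0, 0.0),
        horizontal_radius=a_px,
        vertical_radius=b_px,
        fill_color=fill_color,
        navel_notch_angle=navel_angle_deg,
        top_protrusion_angle=top_angle_deg,
        notch_depth_frac=notch_depth_frac,
        speckle=speckle,
    )


def make_horizontal_fruit(
    r_px: float,
    n_locules: int,
    pericarp_px: float,
    rng: np.random.Generator,
    *,
    flesh_color: tuple[int, int, int] = FLESH_RGB,
    locule_color: tuple[int, int, int] = LOCULE_RGB,
    inner_frac: float = 0.18,
    speckle: int = 0,
    slit_width_px: int = 0,
) -> FruitSpec:
    """Horizontal-cut section: a disk with ``n_locules`` radially arranged
    elliptical locules whose outer edges sit ``pericarp_px`` inside the rim."""
    if n_locules < 1:
        raise InvalidSpecError("n_locules must be >= 1")
    r_in = inner_frac * r_px
    r_out = r_px - pericarp_px
    if r_out <= r_in + 6:
        raise InvalidSpecError("pericarp too thick for the section radius")
    rho0 = 0.5 * (r_in + r_out)
    rad_semi = 0.46 * (r_out - r_in)
    base = rng.uniform(0.0, 2.0 * math.pi)

    def draw_layout(jitter: float) -> list[np.ndarray]:
        rings = []
        for k in range(n_locules):
            ang = base + 2.0 * math.pi * k / n_locules
            if n_locules > 1:
                ang += rng.uniform(-jitter, jitter) * (2.0 * math.pi / n_locules)
            rho = rho0 * rng.uniform(0.95, 1.05)
            rho = min(rho, r_out - rad_semi - 2.0)
            if n_locules > 1:
                tang_semi = min(rho * math.sin(math.pi / n_locules) * 0.62,
                                rad_semi * 1.6)
            else:
                tang_semi = rad_semi * 1.2
            tang_semi = max(tang_semi, 4.0)
            rings.append(ellipse_ring(rho * math.cos(ang), rho * math.sin(ang),
                                      rad_semi, tang_semi, 48, rotation=ang))
        return rings

    def separated(rings: list[np.ndarray]) -> bool:
        polys = [polygon_of(r) for r in rings]
        return all(polys[i].distance(polys[j]) >= 4.0
                   for i in range(len(polys)) for j in range(i + 1, len(polys)))

    # Jittered layouts can collide for crowded locule counts; retry with
    # shrinking jitter, falling back to the always-valid symmetric layout.
    rings = draw_layout(0.08)
    for jitter in (0.05, 0.02, 0.0):
        if separated(rings):
            break
        rings = draw_layout(jitter)
    locules = [LoculeSpec(ring, locule_color) for ring in rings]
    return FruitSpec(
        center=(0.0, 0.0),
        horizontal_radius=r_px,
        vertical_radius=r_px,
        fill_color=flesh_color,
        locules=locules,
        pericarp_thickness_px=pericarp_px,
        speckle=speckle,
        slit_width_px=slit_width_px,
    )


def concentric_locule_fruit(
    r_px: float,
    locule_r_px: float,
    *,
    flesh_color: tuple[int, int, int] = FLESH_RGB,
    locule_color: tuple[int, int, int] = LOCULE_RGB,
) -> FruitSpec:
    """Disk section with a single concentric circular locule (analytic case:
    area proportion (r_loc/r)^2, pericarp gap r - r_loc)."""
    ring = ellipse_ring(0.0, 0.0, locule_r_px, locule_r_px, 256)
    return FruitSpec(
        center=(0.0, 0.0),
        horizontal_radius=r_px,
        vertical_radius=r_px,
        fill_color=flesh_color,
        locules=[LoculeSpec(ring, locule_color)],
        pericarp_thickness_px=r_px - locule_r_px,
    )


def _layout(
    kind: SceneKind,
    fruits: Sequence[FruitSpec],
    pixels_per_cm: float,
    *,
    margin: float = 16.0,
    background_color: tuple[int, int, int] = (255, 255, 255),
) -> SyntheticSceneSpec:
    """Place origin-centred fruits left-to-right and size the canvas to fit."""
    placed = []
    bounds = [f.footprint(kind).bounds for f in fruits]
    heights = [maxy - miny for (_, miny, _, maxy) in bounds]
    hmax = max(heights)
    x_cursor = margin
    for f, (minx, miny, maxx, maxy) in zip(fruits, bounds):
        cy = margin + 0.5 * (hmax - (maxy - miny)) - miny
        cx = x_cursor - minx
        placed.append(replace(f, center=(cx, cy),
                              locules=[LoculeSpec(l.polygon + np.array([cx, cy]),
                                                  l.fill_color) for l in f.locules]))
        x_cursor += (maxx - minx) + margin
    w = int(math.ceil(x_cursor)) + 2
    h = int(math.ceil(hmax + 2 * margin)) + 2
    return SyntheticSceneSpec(
        scene_kind=kind,
        image_size=(w, h),
        pixels_per_cm=pixels_per_cm,
        fruits=placed,
        background_color=background_color,
    )


#: Fill palette spanning the cultivar colour classes (red, orange, yellow,
#: green, dark brownish-red); all hues inside the preset window.
PALETTE = [
    (210, 55, 45),
    (235, 140, 45),
    (230, 200, 60),
    (140, 190, 90),
    (150, 80, 60),
]


def make_intact_scene(
    n_fruits: int = 3,
    seed: int = 0,
    *,
    pixels_per_cm: float = 50.0,
    radius_cm: tuple[float, float] = (1.5, 2.4),
    speckle: int = 0,
) -> SyntheticSceneSpec:
    rng = np.random.default_rng(seed)
    fruits = []
    for i in range(n_fruits):
        a = rng.uniform(*radius_cm) * pixels_per_cm
        b = a * rng.uniform(0.85, 1.15)
        fruits.append(FruitSpec(
            center=(0.0, 0.0), horizontal_radius=a, vertical_radius=b,
            fill_color=PALETTE[i % len(PALETTE)], speckle=speckle,
        ))
    return _layout("intact", fruits, pixels_per_cm)


def make_vertical_scene(
    n_fruits: int = 3,
    seed: int = 0,
    *,
    pixels_per_cm: float = 50.0,
    half_width_cm: tuple[float, float] = (1.8, 2.4),
    navel_deg: tuple[float, float] = (50.0, 85.0),
    top_deg: tuple[float, float] = (95.0, 125.0),
    shape_ratio: tuple[float, float] = (1.15, 1.45),
    speckle: int = 5,
) -> SyntheticSceneSpec:
    rng = np.random.default_rng(seed)
    fruits = []
    for i in range(n_fruits):
        fruits.append(make_vertical_fruit(
            a_px=rng.uniform(*half_width_cm) * pixels_per_cm,
            shape_ratio=rng.uniform(*shape_ratio),
            navel_angle_deg=rng.uniform(*navel_deg),
            top_angle_deg=rng.uniform(*top_deg),
            fill_color=PALETTE[i % len(PALETTE)],
            speckle=speckle,
        ))
    return _layout("vertical", fruits, pixels_per_cm)


def make_horizontal_scene(
    n_fruits: int = 3,
    seed: int = 0,
    *,
    pixels_per_cm: float = 50.0,
    radius_cm: tuple[float, float] = (1.7, 2.3),
    pericarp_frac: tuple[float, float] = (0.3, 0.5),
    locule_range: tuple[int, int] = (2, 6),
    speckle: int = 5,
    locule_counts: Sequence[int] | None = None,
) -> SyntheticSceneSpec:
    """Horizontal-cut scene. The pericarp is drawn as a fraction of the
    section radius so the locule annulus never collapses for small fruits."""
    rng = np.random.default_rng(seed)
    fruits = []
    for i in range(n_fruits):
        n_loc = (locule_counts[i] if locule_counts is not None
                 else int(rng.integers(locule_range[0], locule_range[1] + 1)))
        r_px = rng.uniform(*radius_cm) * pixels_per_cm
        fruits.append(make_horizontal_fruit(
            r_px=r_px,
            n_locules=n_loc,
            pericarp_px=rng.uniform(*pericarp_frac) * r_px,
            rng=rng,
            speckle=speckle,
        ))
    return _layout("horizontal", fruits, pixels_per_cm)


def make_vertical_cohort(
    n_fruits: int, seed: int = 0, *, pixels_per_cm: float = 50.0,
    fruits_per_scene: int = 3, **kwargs,
) -> list[SyntheticSceneSpec]:
    """Well-separated vertical-cut cohort: ``n_fruits`` fruits across scenes."""
    scenes = []
    remaining = n_fruits
    i = 0
    while remaining > 0:
        k = min(fruits_per_scene, remaining)
        scenes.append(make_vertical_scene(
            k, seed=seed * 100003 + i, pixels_per_cm=pixels_per_cm, **kwargs))
        remaining -= k
        i += 1
    return scenes


def make_horizontal_cohort(
    n_fruits: int, seed: int = 0, *, pixels_per_cm: float = 50.0,
    fruits_per_scene: int = 3, **kwargs,
) -> list[SyntheticSceneSpec]:
    scenes = []
    remaining = n_fruits
    i = 0
    while remaining > 0:
        k = min(fruits_per_scene, remaining)
        scenes.append(make_horizontal_scene(
            k, seed=seed * 100003 + i, pixels_per_cm=pixels_per_cm, **kwargs))
        remaining -= k
        i += 1
    return scenes


def make_augmentation_sources(
    n_images: int, seed: int = 0, *, image_size: tuple[int, int] = (256, 256),
) -> list[tuple[np.ndarray, AnnotationSet]]:
    """Annotated horizontal-cut source images on a fixed small canvas,
    as used to exercise the dataset-augmentation arithmetic."""
    w, h = image_size
    ppcm = 28.0
    out = []
    for i in range(n_images):
        rng = np.random.default_rng(seed * 99991 + i)
        fruits = []
        for cx in (w * 0.27, w * 0.73):
            r = rng.uniform(36.0, 50.0)
            fruits.append(replace(
                make_horizontal_fruit(
                    r_px=r,
                    n_locules=int(rng.integers(2, 6)),
                    pericarp_px=rng.uniform(14.0, 20.0),
                    rng=rng,
                    speckle=4,
                ),
                center=(cx, h / 2.0),
            ))
        # re-anchor locule polygons to the placed centres
        for f in fruits:
            f.locules = [LoculeSpec(l.polygon + np.asarray(f.center), l.fill_color)
                         for l in f.locules]
        spec = SyntheticSceneSpec("horizontal", image_size, ppcm, fruits)
        img, _, ann = render_scene(spec, seed=seed * 99991 + i)
        ann.image_id = f"aug_src_{i:04d}"
        out.append((img, ann))
    return out
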