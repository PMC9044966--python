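"""Contour simplification, landmark detection and vertical-cut measurement."""

import math

import numpy as np
import pytest

import tomatophen as tp
from tomatophen import synthetic as syn
from tomatophen.errors import DegenerateContourError, NoNavelError
from tomatophen.synthetic import FruitSpec, SyntheticSceneSpec
from tomatophen.vertical import (
    approximate_polygon,
    find_navel_point,
    find_top_point,
    measure_vertical_phenotype,
    vertex_angle,
)


def _dense_ring(vertices, step=1.0):
    """Sample a closed polygon boundary densely (like a traced contour)."""
    vertices = np.asarray(vertices, dtype=float)
    points = []
    for i in range(len(vertices)):
        a, b = vertices[i], vertices[(i + 1) % len(vertices)]
        n = max(int(np.linalg.norm(b - a) / step), 1)
        for t in np.linspace(0, 1, n, endpoint=False):
            points.append(a + t * (b - a))
    return np.asarray(points)


def _circle_contour(r=100.0, c=(150.0, 150.0), n=720):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([c[0] + r * np.cos(t), c[1] + r * np.sin(t)])


class TestApproximatePolygon:
    def test_square_keeps_four_convex_corners(self):
        contour = _dense_ring([(0, 0), (100, 0), (100, 100), (0, 100)])
        poly = approximate_polygon(contour, 0.02)
        assert len(poly) == 4
        assert poly.convex.all()

    def test_notched_square_has_exactly_one_concave_vertex(self):
        # inward triangular notch in the bottom edge
        contour = _dense_ring([
            (0, 0), (100, 0), (100, 100), (65, 100), (50, 70), (35, 100), (0, 100),
        ])
        poly = approximate_polygon(contour, 0.01)
        concave = poly.vertices[~poly.convex]
        assert len(concave) == 1
        np.testing.assert_allclose(concave[0], (50, 70), atol=1.5)

    def test_circle_vertices_all_convex_against_turn_oracle(self):
        """Cross-check convexity labels with an independent turn computation."""
        poly = approximate_polygon(_circle_contour(), 0.02)
        v = poly.vertices
        prev = np.roll(v, 1, axis=0)
        nxt = np.roll(v, -1, axis=0)
        u, w = v - prev, nxt - v
        cross = u[:, 0] * w[:, 1] - u[:, 1] * w[:, 0]
        # brute-force orientation: all turns share the ring's winding sign
        assert np.all(np.sign(cross) == np.sign(cross[0]))
        assert poly.convex.all()

    def test_short_contour_rejected(self):
        with pytest.raises(DegenerateContourError):
            approximate_polygon(np.array([[0.0, 0.0], [1.0, 1.0]]), 0.02)

    def test_epsilon_range_validated(self):
        with pytest.raises(ValueError):
            approximate_polygon(_circle_contour(), 0.5)


class TestVertexAngle:
    @pytest.mark.parametrize("left,right,expected", [
        ((1, 0), (0, 1), 90.0),
        ((1, 0), (-1, 0), 180.0),
        ((1, 0), (1, 1), 45.0),
    ])
    def test_analytic_angles(self, left, right, expected):
        assert vertex_angle((0, 0), left, right) == pytest.approx(expected, abs=1e-9)

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateContourError):
            vertex_angle((0, 0), (0, 0), (1, 1))


def _single_fruit_scene(fruit, ppcm=50.0, margin=40.0):
    poly = fruit.vertical_polygon()
    minx, miny, maxx, maxy = poly.bounds
    dx, dy = margin - minx, margin - miny
    fruit = syn.replace(fruit, center=(fruit.center[0] + dx, fruit.center[1] + dy))
    w = int(maxx - minx + 2 * margin)
    h = int(maxy - miny + 2 * margin)
    return SyntheticSceneSpec("vertical", (w, h), ppcm, [fruit])


def _measure_single(spec, seed=0):
    img, records, _ = syn.render_scene(spec, seed=seed)
    preset = tp.builtin_presets()["pure_color"]
    inst = tp.extract_fruit_instances(tp.hsv_filter(img, preset))[0]
    scale = tp.PixelScale(spec.pixels_per_cm)
    return img, records[0], inst, measure_vertical_phenotype(img, inst, scale)


class TestLandmarks:
    def test_single_notch_apex_found(self):
        fruit = syn.make_vertical_fruit(100.0, 1.3, 60.0, 110.0)
        spec = _single_fruit_scene(fruit)
        _, record, _, phen = _measure_single(spec)
        np.testing.assert_allclose(phen.landmarks.navel_point, record.navel_point,
                                   atol=3.0)

    def test_saturation_disambiguation_between_equal_notches(self):
        """Two geometrically identical notches: the whitish (low-saturation)
        one near the calyx must win."""
        cx, cy, a, b = 150.0, 150.0, 120.0, 120.0
        ring = syn.ellipse_ring(cx, cy, a, b, 720)
        half = math.radians(30.0)
        reach = 4 * b

        def wedge(apex, direction):
            return syn.Polygon([
                apex,
                (apex[0] - reach * math.sin(half), apex[1] + direction * reach * math.cos(half)),
                (apex[0] + reach * math.sin(half), apex[1] + direction * reach * math.cos(half)),
            ])

        d = 0.3 * b
        bottom_apex = (cx, cy + b - d)
        top_apex = (cx, cy - b + d)
        body = syn.polygon_of(ring).difference(wedge(bottom_apex, +1))
        body = body.difference(wedge(top_apex, -1))
        img = np.full((300, 300, 3), 255, dtype=np.uint8)
        mask = syn._fill_polygon(img, body, syn.FLESH_RGB)
        # paint the pale band inside the bottom notch only
        yy, xx = np.mgrid[0:300, 0:300]
        band = ((xx - bottom_apex[0]) ** 2 + (yy - bottom_apex[1]) ** 2 <= 25**2) & mask
        img[band] = syn.BAND_RGB

        preset = tp.builtin_presets()["pure_color"]
        inst = tp.extract_fruit_instances(tp.hsv_filter(img, preset))[0]
        poly = approximate_polygon(inst.contour)
        from tomatophen.isolation import hsv_channels

        h, s, v = hsv_channels(img)
        navel, _ = find_navel_point(poly, np.dstack([h, s, v]), inst.mask)
        np.testing.assert_allclose(navel, bottom_apex, atol=4.0)

    def test_pure_ellipse_has_no_navel(self):
        fruit = FruitSpec(center=(150.0, 120.0), horizontal_radius=120.0,
                          vertical_radius=90.0)
        spec = SyntheticSceneSpec("vertical", (300, 240), 50.0, [fruit])
        img, _, _ = syn.render_scene(spec, seed=0)
        preset = tp.builtin_presets()["pure_color"]
        inst = tp.extract_fruit_instances(tp.hsv_filter(img, preset))[0]
        with pytest.raises(NoNavelError):
            find_navel_point(approximate_polygon(inst.contour))

    def test_top_point_is_antipode_on_notched_circle(self):
        fruit = FruitSpec(center=(0.0, 0.0), horizontal_radius=100.0,
                          vertical_radius=100.0, navel_notch_angle=60.0,
                          notch_depth_frac=0.2)
        spec = _single_fruit_scene(fruit)
        _, record, inst, phen = _measure_single(spec)
        np.testing.assert_allclose(phen.landmarks.top_point,
                                   record.top_point, atol=3.0)

    def test_top_point_is_protrusion_apex(self):
        fruit = syn.make_vertical_fruit(90.0, 1.4, 70.0, 100.0)
        spec = _single_fruit_scene(fruit)
        _, record, _, phen = _measure_single(spec)
        np.testing.assert_allclose(phen.landmarks.top_point, record.top_point,
                                   atol=3.0)


class TestMeasurement:
    def test_ellipse_with_notch_diameters(self):
        fruit = FruitSpec(center=(0.0, 0.0), horizontal_radius=150.0,
                          vertical_radius=100.0, navel_notch_angle=60.0,
                          notch_depth_frac=0.2)
        spec = _single_fruit_scene(fruit)
        _, record, _, phen = _measure_single(spec)
        assert phen.horizontal_diameter_cm == pytest.approx(6.0, rel=0.02)
        assert phen.vertical_diameter_cm == pytest.approx(
            record.vertical_diameter_cm, rel=0.02)

    def test_rotation_leaves_diameters_within_two_percent(self):
        from skimage.transform import rotate

        spec = syn.make_vertical_scene(1, seed=3)
        img, _, _ = syn.render_scene(spec, seed=3)
        preset = tp.builtin_presets()["pure_color"]
        scale = tp.PixelScale(spec.pixels_per_cm)
        inst = tp.extract_fruit_instances(tp.hsv_filter(img, preset))[0]
        base = measure_vertical_phenotype(img, inst, scale)
        rimg = rotate(img, 30, resize=True, order=0, preserve_range=True,
                      cval=255).astype(np.uint8)
        rinst = tp.extract_fruit_instances(tp.hsv_filter(rimg, preset))[0]
        got = measure_vertical_phenotype(rimg, rinst, scale)
        assert got.horizontal_diameter_cm == pytest.approx(
            base.horizontal_diameter_cm, rel=0.02)
        assert got.vertical_diameter_cm == pytest.approx(
            base.vertical_diameter_cm, rel=0.02)
        assert got.top_angle_deg == pytest.approx(base.top_angle_deg, abs=3.0)
        assert got.navel_angle_deg == pytest.approx(base.navel_angle_deg, abs=3.0)

    def test_angle_recovery_navel_60_top_170(self):
        """A strongly prolate fruit with a nearly flat top: both landmark
        angles recovered within five degrees."""
        fruit = syn.make_vertical_fruit(50.0, 1.0, 60.0, 170.0,
                                        dominance_margin_px=2.0,
                                        notch_depth_frac=0.12)
        spec = _single_fruit_scene(fruit)
        _, record, _, phen = _measure_single(spec)
        assert record.top_angle_deg == 170.0
        assert phen.top_angle_deg == pytest.approx(170.0, abs=5.0)
        assert phen.navel_angle_deg == pytest.approx(60.0, abs=5.0)

    def test_shape_index_of_notched_circle_is_one(self):
        fruit = FruitSpec(center=(0.0, 0.0), horizontal_radius=150.0,
                          vertical_radius=150.0, navel_notch_angle=60.0,
                          notch_depth_frac=0.15)
        spec = _single_fruit_scene(fruit)
        _, _, _, phen = _measure_single(spec)
        assert phen.shape_index == pytest.approx(1.0, abs=0.03)

    def test_ratio_identities_hold_exactly(self, vertical_scene):
        spec, img, _ = vertical_scene
        preset = tp.builtin_presets()["pure_color"]
        scale = tp.PixelScale(spec.pixels_per_cm)
        for inst in tp.extract_fruit_instances(tp.hsv_filter(img, preset)):
            phen = measure_vertical_phenotype(img, inst, scale)
            assert phen.shape_index == pytest.approx(
                phen.vertical_diameter_cm / phen.horizontal_diameter_cm, rel=1e-12)
            assert phen.top_navel_ratio == pytest.approx(
                phen.top_angle_deg / phen.navel_angle_deg, rel=1e-12)

    def test_no_navel_fallback_warns(self):
        fruit = FruitSpec(center=(150.0, 120.0), horizontal_radius=100.0,
                          vertical_radius=90.0)
        spec = SyntheticSceneSpec("vertical", (300, 240), 50.0, [fruit])
        img, _, _ = syn.render_scene(spec, seed=0)
        preset = tp.builtin_presets()["pure_color"]
        inst = tp.extract_fruit_instances(tp.hsv_filter(img, preset))[0]
        phen = measure_vertical_phenotype(img, inst, tp.PixelScale(50.0))
        assert "no-navel-fallback" in phen.warnings

    def test_missing_scale_is_a_calibration_error(self, vertical_scene):
        spec, img, _ = vertical_scene
        preset = tp.builtin_presets()["pure_color"]
        inst = tp.extract_fruit_instances(tp.hsv_filter(img, preset))[0]
        with pytest.raises(tp.CalibrationError):
            measure_vertical_phenotype(img, inst, None)
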