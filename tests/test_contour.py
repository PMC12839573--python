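"""Discrete geometry primitives: lengths, areas, centroids, curvature, winding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shapesect import (
    Contour,
    ParamMap,
    apply_param_map,
    area_centroid,
    contour_centroid,
    point_in_polygon,
    polyline_length,
    signed_area,
    signed_curvature,
    winding_angle,
)
from shapesect.contour import turning_angles
from shapesect.errors import (
    DegenerateAreaError,
    ExteriorReferenceError,
    InvalidContourError,
    InvalidMapError,
)

from conftest import make_circle


class TestLengthArea:
    def test_unit_square(self, unit_square):
        assert polyline_length(unit_square) == pytest.approx(4.0)
        assert signed_area(unit_square) == pytest.approx(1.0)

    def test_inscribed_ngon_perimeter_closed_form(self):
        n = 1000
        c = make_circle(radius=1.0, n=n)
        assert polyline_length(c) == pytest.approx(2 * n * np.sin(np.pi / n), rel=1e-12)

    def test_orientation_reversal_flips_area_keeps_length(self, unit_square):
        rev = Contour(unit_square.vertices[::-1])
        assert polyline_length(rev) == polyline_length(unit_square)
        assert signed_area(rev) == pytest.approx(-1.0)

    def test_triangle_area(self):
        tri = Contour([[0, 0], [1, 0], [0, 1]])
        assert signed_area(tri) == pytest.approx(0.5)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_rigid_motion_and_roll_invariance(self, seed):
        rng = np.random.default_rng(seed)
        c = make_circle(radius=1.0, n=64)
        v = c.vertices + 0.05 * rng.standard_normal((64, 2))
        c = Contour(v)
        ang = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        shift = rng.uniform(-5, 5, 2)
        k = int(rng.integers(0, 64))
        moved = Contour(np.roll(v @ rot.T + shift, k, axis=0))
        assert polyline_length(moved) == pytest.approx(polyline_length(c), rel=1e-9)
        assert abs(signed_area(moved)) == pytest.approx(abs(signed_area(c)), rel=1e-9)
        scaled = Contour(3.0 * v)
        assert polyline_length(scaled) == pytest.approx(3 * polyline_length(c), rel=1e-12)
        assert signed_area(scaled) == pytest.approx(9 * signed_area(c), rel=1e-12)

    def test_too_few_vertices_rejected(self):
        with pytest.raises(InvalidContourError):
            Contour([[0, 0], [1, 1]])
        with pytest.raises(InvalidContourError):
            Contour([[0, 0], [0, 0], [1, 1], [1, 0]])


class TestCentroids:
    def test_circle_centroids_at_center(self):
        c = make_circle(radius=1.0, n=500, center=(2.0, 3.0))
        assert contour_centroid(c) == pytest.approx([2.0, 3.0], abs=1e-9)
        assert area_centroid(c) == pytest.approx([2.0, 3.0], abs=1e-9)

    def test_square_centroids(self, unit_square):
        assert contour_centroid(unit_square) == pytest.approx([0.5, 0.5])
        assert area_centroid(unit_square) == pytest.approx([0.5, 0.5])

    def test_triangle_area_centroid(self):
        tri = Contour([[0, 0], [1, 0], [0, 1]])
        assert area_centroid(tri) == pytest.approx([1 / 3, 1 / 3])

    def test_l_hexagon_contour_centroid_against_edge_quadrature(self, l_hexagon):
        # independent per-edge line-integral oracle
        v = np.vstack([l_hexagon.vertices, l_hexagon.vertices[:1]])
        total, acc = 0.0, np.zeros(2)
        for a, b in zip(v[:-1], v[1:]):
            ell = np.linalg.norm(b - a)
            acc += 0.5 * (a + b) * ell
            total += ell
        assert contour_centroid(l_hexagon) == pytest.approx(acc / total, rel=1e-12)

    def test_l_hexagon_area_centroid_by_decomposition(self, l_hexagon):
        # two rectangles: [0,2]x[0,1] (area 2, centroid (1,.5)), [0,1]x[1,2]
        expected = (2 * np.array([1.0, 0.5]) + 1 * np.array([0.5, 1.5])) / 3
        assert area_centroid(l_hexagon) == pytest.approx(expected, rel=1e-12)
        # orientation independent
        rev = Contour(l_hexagon.vertices[::-1])
        assert area_centroid(rev) == pytest.approx(expected, rel=1e-12)

    def test_contour_centroid_resampling_invariant(self):
        from shapesect import arclength_map

        c = make_circle(radius=2.0, n=400)
        dense = apply_param_map(c, arclength_map(c), 1200)
        assert contour_centroid(dense) == pytest.approx(contour_centroid(c), abs=1e-9)

    def test_degenerate_area_raises(self):
        flat = Contour([[0, 0], [1, 0], [2, 0], [1, 1e-16]])
        with pytest.raises(DegenerateAreaError):
            area_centroid(flat)


class TestCurvature:
    def test_circle_curvature_one_over_r(self):
        c = make_circle(radius=2.0, n=1000)
        assert signed_curvature(c) == pytest.approx(0.5, abs=1e-3)

    def test_collinear_vertex_zero_curvature(self):
        c = Contour([[0, 0], [1, 0], [2, 0], [2, 1], [0, 1]])
        assert signed_curvature(c)[1] == pytest.approx(0.0, abs=1e-12)

    def test_reversal_negates_profile(self):
        c = make_circle(radius=1.0, n=64)
        v = c.vertices + 0.03 * np.sin(5 * np.linspace(0, 2 * np.pi, 64, endpoint=False))[:, None]
        c = Contour(v)
        rev = Contour(np.vstack([v[:1], v[:0:-1]]))
        k_fwd = signed_curvature(c)
        k_rev = signed_curvature(rev)
        # vertex i of rev is vertex -i of c
        realigned = np.concatenate([k_rev[:1], k_rev[:0:-1]])
        assert realigned == pytest.approx(-k_fwd, rel=1e-9, abs=1e-12)

    def test_total_turning_is_two_pi(self, stadium):
        assert turning_angles(stadium).sum() == pytest.approx(2 * np.pi, abs=1e-6)


class TestWindingAngle:
    def test_ccw_circle_from_top_is_linear(self):
        c = make_circle(radius=1.0, n=720, start_top=True)
        w = winding_angle(c, np.zeros(2))
        t = np.arange(721) / 720
        assert w == pytest.approx(2 * np.pi * t, abs=1e-6)

    def test_cw_circle_ends_at_minus_two_pi(self):
        c = make_circle(radius=1.0, n=360, ccw=False)
        w = winding_angle(c, np.zeros(2))
        assert w[-1] == pytest.approx(-2 * np.pi, abs=1e-9)

    def test_ellipse_against_dense_atan2_oracle(self):
        th = 2 * np.pi * np.arange(1000) / 1000
        c = Contour(np.column_stack([2 * np.cos(th), np.sin(th)]))
        w = winding_angle(c, np.zeros(2))
        # brute-force unwrapping oracle
        ang = np.arctan2(np.sin(th), 2 * np.cos(th))
        ang = np.concatenate([ang, ang[:1]])
        expect = np.zeros(1001)
        for i in range(1, 1001):
            d = ang[i] - ang[i - 1]
            while d <= -np.pi:
                d += 2 * np.pi
            while d > np.pi:
                d -= 2 * np.pi
            expect[i] = expect[i - 1] + d
        assert w == pytest.approx(expect, abs=1e-9)

    def test_exterior_reference_rejected(self, unit_square):
        with pytest.raises(ExteriorReferenceError):
            winding_angle(unit_square, np.array([5.0, 5.0]))


class TestPointInPolygon:
    def test_square_interior_exterior(self, unit_square):
        assert point_in_polygon(np.array([0.5, 0.5]), unit_square)
        assert not point_in_polygon(np.array([2.0, 2.0]), unit_square)
        assert not point_in_polygon(np.array([0.0, 0.5]), unit_square)  # boundary

    def test_crescent_area_centroid_exterior(self):
        from shapesect import make_crescent

        cr = make_crescent()
        assert not point_in_polygon(area_centroid(cr), cr)
        # ray-casting oracle for the same point
        p = area_centroid(cr)
        v = np.vstack([cr.vertices, cr.vertices[:1]])
        crossings = 0
        for a, b in zip(v[:-1], v[1:]):
            if (a[1] > p[1]) != (b[1] > p[1]):
                x = a[0] + (p[1] - a[1]) / (b[1] - a[1]) * (b[0] - a[0])
                if x > p[0]:
                    crossings += 1
        assert crossings % 2 == 0


class TestParamMap:
    def test_identity_roundtrip_bit_exact(self):
        c = make_circle(radius=1.0, n=48)
        m = ParamMap.identity(49)
        out = apply_param_map(c, m, 48)
        assert np.array_equal(out.vertices, c.vertices)

    def test_t_squared_map_on_circle(self):
        n = 1000
        c = make_circle(radius=1.0, n=n)
        grid = np.linspace(0, 1, n + 1)
        m = ParamMap(grid**2)
        out = apply_param_map(c, m, 1000)
        j = np.arange(1000)
        expect = np.column_stack([
            np.cos(2 * np.pi * np.sqrt(j / 1000)), np.sin(2 * np.pi * np.sqrt(j / 1000))
        ])
        assert np.abs(out.vertices - expect).max() < 1e-3

    def test_inverse_roundtrip_recovers_uniform_sampling(self):
        # dense sampling keeps the polyline chord error below the tolerance
        n = 6000
        c = make_circle(radius=1.0, n=n)
        grid = np.linspace(0, 1, n + 1)
        m = ParamMap(grid + 0.05 * np.sin(2 * np.pi * grid))
        warped = apply_param_map(c, m, n)
        inv = ParamMap(m.invert(grid))
        back = apply_param_map(warped, inv, n)
        assert np.abs(back.vertices - c.vertices).max() < 1e-6

    def test_non_monotone_map_rejected(self):
        with pytest.raises(InvalidMapError):
            ParamMap([0.0, 0.6, 0.4, 1.0])
        with pytest.raises(InvalidMapError):
            ParamMap([0.1, 0.5, 1.0])

    def test_plateau_inverted_to_left_edge(self):
        m = ParamMap([0.0, 0.5, 0.5, 0.5, 1.0])
        assert m.invert(np.array([0.5]))[0] == pytest.approx(0.25)
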