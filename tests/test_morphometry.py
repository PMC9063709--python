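"""Moments, best-fit-ellipse axes, hull geometry and object measurement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from inflorascan import (
    boundary_pixels,
    central_moments,
    convex_hull,
    ellipse_axes,
    measure_object,
    polygon_area,
    polygon_perimeter,
)
from inflorascan.morphometry import pixel_corners

from conftest import (
    brute_force_hull_vertices,
    fan_triangulation_area,
    rasterize_ellipse,
)


class TestCentralMoments:
    def test_single_point(self):
        m = central_moments([(5.0, 7.0)])
        assert (m.u00, m.u20, m.u02, m.u11) == (1, 0, 0, 0)
        assert (m.centroid_x, m.centroid_y) == (5, 7)

    def test_two_point_symmetry(self):
        m = central_moments([(0.0, 0.0), (2.0, 0.0)])
        assert (m.centroid_x, m.centroid_y) == (1, 0)
        assert (m.u20, m.u02, m.u11) == (2, 0, 0)

    def test_three_by_three_block(self):
        pts = [(x, y) for x in range(3) for y in range(3)]
        m = central_moments(pts)
        assert m.u00 == 9
        assert m.u20 == m.u02 == 6  # 3 * (1 + 0 + 1) per axis
        assert m.u11 == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            central_moments(np.empty((0, 2)))


class TestEllipseAxes:
    def test_three_by_three_block_closed_form(self):
        pts = [(x, y) for x in range(3) for y in range(3)]
        length, width = ellipse_axes(central_moments(pts))
        expected = 2 * math.sqrt(2) * math.sqrt(12 / 9)
        assert length == pytest.approx(expected)
        assert width == pytest.approx(expected)

    def test_digitized_disk_diameter(self):
        pts = rasterize_ellipse(50, 50)
        length, width = ellipse_axes(central_moments(pts))
        assert length == pytest.approx(100, rel=0.02)
        assert width == pytest.approx(100, rel=0.02)

    def test_rotated_ellipse_axes(self):
        pts = rasterize_ellipse(60, 25, angle_deg=30)
        length, width = ellipse_axes(central_moments(pts))
        assert length == pytest.approx(120, rel=0.02)
        assert width == pytest.approx(50, rel=0.02)

    def test_rotation_stability(self):
        """Axes vary by < 2% across rotations for a well-resolved ellipse."""
        lengths, widths = [], []
        for angle in range(0, 180, 10):
            pts = rasterize_ellipse(40, 20, angle_deg=angle)
            l, w = ellipse_axes(central_moments(pts))
            lengths.append(l)
            widths.append(w)
        assert np.ptp(lengths) / np.mean(lengths) < 0.02
        assert np.ptp(widths) / np.mean(widths) < 0.02

    def test_boundary_moments_inflate_disk(self):
        """Boundary-only moments overestimate a disk's diameter by ~sqrt(2):
        the 2*sqrt(2) constant is the filled-region calibration."""
        pts = rasterize_ellipse(50, 50)
        ring = boundary_pixels(pts)
        length, _ = ellipse_axes(central_moments(ring))
        assert length == pytest.approx(100 * math.sqrt(2), rel=0.03)

    def test_degenerate_point(self):
        length, width = ellipse_axes(central_moments([(1.0, 1.0)]))
        assert length == 0 and width == 0


class TestBoundaryPixels:
    def test_single_pixel_is_its_own_boundary(self):
        out = boundary_pixels(np.array([[3, 4]]))
        np.testing.assert_array_equal(out, [[3, 4]])

    def test_block_rims(self):
        pts3 = np.array([(x, y) for x in range(3) for y in range(3)])
        assert len(boundary_pixels(pts3)) == 8
        pts10 = np.array([(x, y) for x in range(10) for y in range(10)])
        assert len(boundary_pixels(pts10)) == 36

    def test_subset_of_object(self):
        pts = rasterize_ellipse(12, 7, angle_deg=20)
        ring = boundary_pixels(pts)
        obj = {tuple(p) for p in pts}
        assert all(tuple(p) in obj for p in ring)


class TestConvexHull:
    def test_triangle(self):
        pts = np.array([[0, 0], [4, 0], [0, 3]], dtype=float)
        hull = convex_hull(pts)
        assert {tuple(v) for v in hull} == {(0, 0), (4, 0), (0, 3)}

    def test_interior_point_excluded(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5]])
        hull = convex_hull(pts)
        assert {tuple(v) for v in hull} == {(0, 0), (1, 0), (1, 1), (0, 1)}

    def test_collinear_edge_points_excluded(self):
        pts = np.array([[0, 0], [2, 0], [2, 2], [0, 2], [1, 0], [0, 1]], dtype=float)
        hull = convex_hull(pts)
        assert {tuple(v) for v in hull} == {(0, 0), (2, 0), (2, 2), (0, 2)}

    def test_counter_clockwise_orientation(self):
        rng = np.random.default_rng(0)
        pts = rng.random((30, 2))
        hull = convex_hull(pts)
        x, y = hull[:, 0], hull[:, 1]
        signed = 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))
        assert signed > 0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            pts = rng.random((rng.integers(5, 60), 2))
            got = {tuple(v) for v in convex_hull(pts)}
            assert got == brute_force_hull_vertices(pts)

    def test_degenerate_inputs(self):
        assert convex_hull([(1.0, 2.0)]).shape == (1, 2)
        assert convex_hull([(0.0, 0.0), (1.0, 1.0)]).shape == (2, 2)


class TestPolygonGeometry:
    def test_unit_square(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        assert polygon_area(sq) == 1
        assert polygon_perimeter(sq) == 4

    def test_triangle_area(self):
        tri = np.array([[0, 0], [4, 0], [0, 3]], dtype=float)
        assert polygon_area(tri) == 6

    def test_two_vertex_out_and_back(self):
        seg = np.array([[0, 0], [3, 4]], dtype=float)
        assert polygon_perimeter(seg) == 10
        assert polygon_area(seg) == 0

    def test_area_matches_fan_triangulation(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            hull = convex_hull(rng.random((50, 2)) * 100)
            assert polygon_area(hull) == pytest.approx(
                fan_triangulation_area(hull), rel=1e-9
            )

    @given(st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=25, deadline=None)
    def test_isoperimetric_inequality(self, seed):
        rng = np.random.default_rng(seed)
        hull = convex_hull(rng.random((25, 2)) * 10)
        if hull.shape[0] >= 3:
            a = polygon_area(hull)
            p = polygon_perimeter(hull)
            assert p**2 >= 4 * math.pi * a * (1 - 1e-9)


class TestMeasureObject:
    def test_size_is_exact_pixel_arithmetic(self):
        pts = np.array([(x, y) for x in range(80) for y in range(50)])
        rec = measure_object(pts, cm_per_pixel=0.05)
        assert rec.IS_cm2 == 4000 * 0.05 * 0.05  # same fp product as the code
        assert rec.pixel_count == 4000

    def test_generated_ellipse_absolute_units(self):
        # a = 3 cm, b = 1.5 cm at 0.025 cm/px -> 120 / 60 px semi-axes
        pts = rasterize_ellipse(120, 60, angle_deg=25)
        rec = measure_object(pts, cm_per_pixel=0.025)
        assert rec.IL_cm == pytest.approx(6.0, rel=0.02)
        assert rec.IW_cm == pytest.approx(3.0, rel=0.02)
        assert rec.ISH == pytest.approx(0.5, rel=0.02)

    def test_scale_equivariance_exact(self):
        pts = rasterize_ellipse(30, 18, angle_deg=40)
        r1 = measure_object(pts, cm_per_pixel=0.05)
        r2 = measure_object(pts, cm_per_pixel=0.10)
        assert r2.IL_cm == pytest.approx(2 * r1.IL_cm, rel=1e-12)
        assert r2.IW_cm == pytest.approx(2 * r1.IW_cm, rel=1e-12)
        assert r2.HP_cm == pytest.approx(2 * r1.HP_cm, rel=1e-12)
        assert r2.IS_cm2 == pytest.approx(4 * r1.IS_cm2, rel=1e-12)
        assert r2.CH_cm2 == pytest.approx(4 * r1.CH_cm2, rel=1e-12)
        assert r2.ISH == pytest.approx(r1.ISH, rel=1e-12)

    def test_corner_hull_contains_pixel_area(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            a = rng.uniform(5, 25)
            b = a * rng.uniform(0.3, 1.0)
            pts = rasterize_ellipse(a, b, angle_deg=rng.uniform(0, 180))
            rec = measure_object(pts, cm_per_pixel=0.05)
            assert rec.CH_cm2 >= rec.IS_cm2
            assert rec.IW_cm <= rec.IL_cm
            assert 0 < rec.ISH <= 1

    def test_center_hull_mode_smaller_than_corner_hull(self):
        pts = rasterize_ellipse(15, 9)
        corner = measure_object(pts, 0.05, hull_points="corners")
        center = measure_object(pts, 0.05, hull_points="centers")
        assert center.CH_cm2 < corner.CH_cm2

    def test_single_pixel_flagged_degenerate(self):
        rec = measure_object(np.array([[4, 4]]), cm_per_pixel=0.05)
        assert rec.IL_cm == 0 and rec.IW_cm == 0
        assert math.isnan(rec.ISH)
        assert rec.degenerate

    def test_collinear_pixels_zero_width(self):
        pts = np.array([(x, 0) for x in range(10)])
        rec = measure_object(pts, cm_per_pixel=0.05)
        assert rec.IW_cm == 0
        assert rec.degenerate


def test_pixel_corners_count_and_containment():
    pts = np.array([[0, 0], [1, 0]])
    corners = pixel_corners(pts)
    assert corners.shape == (6, 2)  # 8 corners, 2 shared
    assert corners.min() == -0.5 and corners.max() == 1.5
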