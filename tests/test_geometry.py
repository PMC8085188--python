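"""Geometry: bounded Voronoi diagrams, the Delaunay dual, morphometrics."""

import math

import numpy as np
import pytest
import shapely
from hypothesis import given, settings
from hypothesis import strategies as st

from lobulizer.geometry import (
    PolygonRegion,
    delaunay_dual,
    interior_region_ids,
    min_enclosing_circle_diameter,
    polygon_area,
    rasterize_tessellation,
    regular_polygon_area,
    side_count,
    voronoi_partition,
)


def brute_force_nearest_site(sites, shape):
    """Per-pixel nearest-site labels (ties to the lowest site index)."""
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    best = np.full(shape, np.inf)
    lab = np.zeros(shape, dtype=int)
    for i, (x, y) in enumerate(sites):
        d = (xx - x) ** 2 + (yy - y) ** 2
        closer = d < best
        best[closer] = d[closer]
        lab[closer] = i + 1
    return lab


class TestVoronoiPartition:
    def test_single_site_fills_rectangle(self):
        t = voronoi_partition([[5.0, 5.0]], (10, 10))
        assert len(t.regions) == 1
        assert t.regions[0].pixel_area() == pytest.approx(100.0)

    def test_two_sites_split_by_perpendicular_bisector(self):
        t = voronoi_partition([[2.0, 5.0], [8.0, 5.0]], (10, 10))
        areas = sorted(r.pixel_area() for r in t.regions)
        assert areas == pytest.approx([50.0, 50.0])
        # the shared boundary is the vertical line x = 5
        shared = t.regions[0].polygon.intersection(t.regions[1].polygon)
        xs = np.asarray(shared.coords)[:, 0]
        assert np.allclose(xs, 5.0)

    def test_every_pixel_lies_in_nearest_site_region(self):
        rng = np.random.default_rng(7)
        sites = rng.uniform(4, 60, (5, 2))
        t = voronoi_partition(sites, (64, 64))
        truth = brute_force_nearest_site(sites, (64, 64))
        # polygon of the nearest site must cover the pixel center
        for y in range(64):
            for x in range(64):
                region = t.regions[truth[y, x] - 1]
                assert region.polygon.covers(shapely.Point(x, y))

    def test_raster_labels_match_brute_force(self):
        rng = np.random.default_rng(11)
        sites = rng.uniform(2, 126, (20, 2))
        t = voronoi_partition(sites, (128, 128))
        assert np.array_equal(
            rasterize_tessellation(t, (128, 128)),
            brute_force_nearest_site(sites, (128, 128)),
        )

    def test_duplicate_sites_rejected_with_pair(self):
        with pytest.raises(ValueError, match="0 and 2"):
            voronoi_partition([[1, 1], [5, 5], [1, 1]], (10, 10))

    def test_site_outside_bbox_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            voronoi_partition([[5, 5], [11, 3]], (10, 10))

    @pytest.mark.parametrize("seed", range(5))
    def test_partition_conserves_area(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 40)
        sites = np.column_stack(
            [rng.uniform(1, 199, n), rng.uniform(1, 149, n)]
        )
        t = voronoi_partition(sites, (200, 150))
        total = sum(r.pixel_area() for r in t.regions)
        assert total == pytest.approx(200 * 150, rel=1e-6)

    def test_regions_contain_their_sites_and_are_convex(self):
        rng = np.random.default_rng(3)
        sites = rng.uniform(5, 250, (30, 2))
        t = voronoi_partition(sites, (256, 256))
        for r in t.regions:
            assert r.polygon.covers(shapely.Point(*r.site))
            hull = r.polygon.convex_hull
            assert r.polygon.area == pytest.approx(hull.area, rel=1e-9)


class TestDelaunayDual:
    def test_two_sites_one_edge(self):
        t = voronoi_partition([[10, 20], [50, 40]], (64, 64))
        assert delaunay_dual(t) == [(0, 1)]

    def test_three_noncollinear_sites_triangle(self):
        t = voronoi_partition([[10, 10], [50, 15], [30, 50]], (64, 64))
        assert delaunay_dual(t) == [(0, 1), (0, 2), (1, 2)]

    def test_matches_empty_circumcircle_oracle(self):
        rng = np.random.default_rng(5)
        sites = rng.uniform(20, 236, (10, 2))
        t = voronoi_partition(sites, (256, 256))
        assert delaunay_dual(t) == sorted(self._delaunay_oracle(sites, (256, 256)))

    @staticmethod
    def _delaunay_oracle(sites, bbox):
        """Brute-force empty-circle adjacency for the bounded diagram.

        Pair (i, j) is adjacent iff there are empty-circle centers on
        their bisector (points equidistant from i and j and no closer to
        any other site) forming a segment of positive length inside the
        rectangle.  Both conditions are linear along the bisector, so
        the segment is an exact interval intersection.
        """
        w, h = bbox
        n = len(sites)
        edges = set()
        for i in range(n):
            for j in range(i + 1, n):
                a, b = sites[i], sites[j]
                m = (a + b) / 2.0
                d = b - a
                u = np.array([-d[1], d[0]]) / np.hypot(*d)  # bisector direction
                lo, hi = -np.inf, np.inf
                # closer to i (and j) than to any other site k:
                # |c-k|^2 - |c-i|^2 = alpha + beta*t >= 0 for c = m + t*u
                for k in range(n):
                    if k in (i, j):
                        continue
                    kk = sites[k]
                    alpha = (kk - a) @ (kk - a) / 2.0 - (kk - a) @ (m - a)
                    beta = -((kk - a) @ u)
                    if abs(beta) < 1e-12:
                        if alpha < 0:
                            lo, hi = 1.0, 0.0
                            break
                    elif beta > 0:
                        lo = max(lo, -alpha / beta)
                    else:
                        hi = min(hi, -alpha / beta)
                # inside the rectangle: 0 <= m + t*u <= (w, h), linear in t
                for coord, size in ((0, w), (1, h)):
                    if abs(u[coord]) < 1e-12:
                        if not (0 <= m[coord] <= size):
                            lo, hi = 1.0, 0.0
                        continue
                    t0 = (0 - m[coord]) / u[coord]
                    t1 = (size - m[coord]) / u[coord]
                    lo = max(lo, min(t0, t1))
                    hi = min(hi, max(t0, t1))
                if hi - lo > 1e-9:
                    edges.add((i, j))
        return edges

    @staticmethod
    def _circumcircle(a, b, c):
        d = 2.0 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
        if abs(d) < 1e-12:
            return None, None
        ux = (
            (a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1]) + (c @ c) * (a[1] - b[1])
        ) / d
        uy = (
            (a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0]) + (c @ c) * (b[0] - a[0])
        ) / d
        center = np.array([ux, uy])
        return center, float((a - center) @ (a - center))

    def test_requires_two_sites(self):
        t = voronoi_partition([[5, 5]], (10, 10))
        with pytest.raises(ValueError):
            delaunay_dual(t)


class TestPolygonArea:
    def test_unit_square_at_millimeter_scale(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        assert polygon_area(sq, scale=1000.0) == pytest.approx(1.0)

    def test_pixel_square_at_scan_resolution(self):
        sq = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float)
        assert polygon_area(sq, scale=0.5) == pytest.approx(2.5e-5)

    def test_matches_monte_carlo_oracle(self):
        rng = np.random.default_rng(13)
        pts = rng.uniform(0, 100, (12, 2))
        hull = shapely.MultiPoint(pts).convex_hull
        verts = np.asarray(hull.exterior.coords[:-1])
        samples = rng.uniform(0, 100, (400_000, 2))
        inside = shapely.contains_xy(hull, samples[:, 0], samples[:, 1])
        mc_area = inside.mean() * 100 * 100
        assert polygon_area(verts, scale=1.0) * 1e6 == pytest.approx(mc_area, rel=5e-3)

    def test_self_intersecting_rejected(self):
        bowtie = np.array([[0, 0], [2, 2], [2, 0], [0, 2]], float)
        with pytest.raises(ValueError):
            polygon_area(bowtie, scale=1.0)


class TestSideCount:
    square = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float)

    def test_square(self):
        assert side_count(self.square) == 4

    def test_collinear_midpoint_merged(self):
        with_mid = np.array(
            [[0, 0], [5, 0], [10, 0], [10, 10], [0, 10]], float
        )
        assert side_count(with_mid) == 4

    def test_perturbed_heptagon(self):
        theta = np.arange(7) / 7 * 2 * np.pi
        r = 100.0
        verts = np.column_stack([r * np.cos(theta), r * np.sin(theta)]) + 120
        # 1-degree angular perturbation of every vertex
        rng = np.random.default_rng(17)
        dtheta = np.radians(rng.uniform(-1, 1, 7))
        verts = np.column_stack(
            [r * np.cos(theta + dtheta), r * np.sin(theta + dtheta)]
        ) + 120
        assert side_count(verts, angle_tol=10.0) == 7

    def test_close_vertices_collapsed(self):
        sq = np.array([[0, 0], [10, 0], [10, 9.5], [10, 10], [0, 10]], float)
        assert side_count(sq, merge_dist=2.0) == 4

    def test_degenerate_rejected(self):
        line = np.array([[0, 0], [5, 5], [10, 10]], float)
        with pytest.raises(ValueError):
            side_count(line)


class TestMinEnclosingCircle:
    def test_square_diagonal(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        assert min_enclosing_circle_diameter(sq, scale=1000.0) == pytest.approx(
            math.sqrt(2.0)
        )

    def test_regular_hexagon_is_twice_circumradius(self):
        theta = np.arange(6) / 6 * 2 * np.pi
        hexagon = 600.0 * np.column_stack([np.cos(theta), np.sin(theta)])
        assert min_enclosing_circle_diameter(hexagon, scale=1.0) == pytest.approx(1.2)

    def test_matches_exhaustive_two_three_point_oracle(self):
        rng = np.random.default_rng(19)
        pts = rng.uniform(0, 50, (14, 2))
        expected = self._mec_oracle(pts)
        got = min_enclosing_circle_diameter(pts, scale=1000.0)
        assert got == pytest.approx(expected, rel=1e-9)

    @staticmethod
    def _mec_oracle(pts):
        """Smallest circle through 2 or 3 support points, exhaustively."""
        best = np.inf
        n = len(pts)
        eps = 1e-9
        for i in range(n):
            for j in range(i + 1, n):
                c = (pts[i] + pts[j]) / 2
                r = np.hypot(*(pts[i] - c))
                if np.all(np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1]) <= r + eps):
                    best = min(best, r)
                for k in range(j + 1, n):
                    c, r2 = TestDelaunayDual._circumcircle(pts[i], pts[j], pts[k])
                    if c is None:
                        continue
                    r = math.sqrt(r2)
                    if np.all(
                        np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1]) <= r + eps
                    ):
                        best = min(best, r)
        return 2.0 * best  # mm at scale 1000 µm/px


class TestRegularPolygonArea:
    def test_prototypical_heptagon_lobule(self):
        # heptagon at the average reported human lobule circumradius
        assert regular_polygon_area(7, 0.57) == pytest.approx(0.889, abs=5e-4)

    def test_square_from_unit_circumradius(self):
        assert regular_polygon_area(4, 1.0) == pytest.approx(2.0)

    def test_hexagon_equals_six_equilateral_triangles(self):
        tri = 6 * (math.sqrt(3) / 4)  # six unit-side equilateral triangles
        assert regular_polygon_area(6, 1.0) == pytest.approx(tri, rel=1e-12)

    def test_limit_is_circle_area(self):
        assert regular_polygon_area(10**6, 1.0) == pytest.approx(math.pi, rel=1e-9)

    def test_rejects_degenerate(self):
        with pytest.raises(ValueError):
            regular_polygon_area(2, 1.0)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=10**6))
def test_partition_conserves_area_property(seed):
    """Voronoi cells clipped to the rectangle always tile it exactly."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 25))
    sites = np.column_stack([rng.uniform(0.5, 99.5, n), rng.uniform(0.5, 79.5, n)])
    if n > 1 and np.min(
        np.linalg.norm(sites[:, None] - sites[None, :], axis=-1)
        + np.eye(n) * 1e9
    ) < 1e-6:
        return
    t = voronoi_partition(sites, (100, 80))
    assert sum(r.pixel_area() for r in t.regions) == pytest.approx(8000, rel=1e-6)
    for r in t.regions:
        assert r.polygon.covers(shapely.Point(*r.site))


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    st.integers(min_value=3, max_value=12),
    st.floats(min_value=0.1, max_value=10.0),
)
def test_regular_polygon_side_count_and_area_bounds(n, radius):
    """A regular n-gon reports n sides and area below its circumcircle's."""
    theta = np.arange(n) / n * 2 * np.pi
    verts = 100.0 * radius * np.column_stack([np.cos(theta), np.sin(theta)]) + 1500
    assert side_count(verts, angle_tol=10.0, merge_dist=1e-6) == n
    area = regular_polygon_area(n, radius)
    assert 0 < area < math.pi * radius**2


def test_hexagonal_lattice_interior_cells_have_six_sides():
    pitch = 40.0
    dy = pitch * math.sqrt(3) / 2
    pts = []
    for j in range(7):
        x0 = pitch / 2 if j % 2 else pitch
        pts += [(x0 + i * pitch, dy / 2 + j * dy) for i in range(7)]
    pts = np.array([p for p in pts if p[0] < 280 and p[1] < 240])
    t = voronoi_partition(pts, (280, 240))
    interior = interior_region_ids(t, margin=1.0)
    assert len(interior) >= 10
    for rid in interior:
        assert side_count(t.region_by_id(rid)) == 6
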