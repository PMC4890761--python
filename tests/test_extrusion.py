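"""Block-model construction: point selection, medians, bases, volumes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Polygon, box

import blockpop as bp
from blockpop.extrusion import ExtrusionError


# --- independent oracles ---------------------------------------------------

def ray_casting_contains(poly_coords, x, y):
    """Classic even-odd ray casting with the half-open edge convention on y."""
    inside = False
    n = len(poly_coords)
    for i in range(n):
        x1, y1 = poly_coords[i]
        x2, y2 = poly_coords[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xi = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
            if x < xi:
                inside = not inside
    return inside


def triangulation_fan_area(coords):
    """Area of a convex polygon as a fan of triangles from vertex 0."""
    x0, y0 = coords[0]
    total = 0.0
    for (x1, y1), (x2, y2) in zip(coords[1:-1], coords[2:]):
        total += abs((x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0)) / 2
    return total


def random_star_polygon(rng, n=8, radius=5.0):
    """A simple (star-shaped) polygon: random radii at sorted angles."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n))
    radii = rng.uniform(0.3 * radius, radius, n)
    return [(r * np.cos(a), r * np.sin(a)) for r, a in zip(radii, angles)]


# --- points_in_footprint ----------------------------------------------------

class TestPointsInFootprint:
    def test_unit_square_boundary_inclusive(self):
        square = box(0, 0, 1, 1)
        cloud = np.array([[0.5, 0.5, 3.0], [2.0, 2.0, 3.0], [1.0, 0.5, 3.0]])
        kept = bp.points_in_footprint(cloud, square)
        assert kept.shape == (2, 3)
        assert {tuple(p[:2]) for p in kept} == {(0.5, 0.5), (1.0, 0.5)}

    def test_empty_cloud(self):
        assert bp.points_in_footprint(np.empty((0, 3)), box(0, 0, 1, 1)).shape == (0, 3)

    def test_degenerate_polygon_rejected(self):
        line = Polygon([(0, 0), (1, 0), (2, 0)])
        with pytest.raises(ExtrusionError):
            bp.points_in_footprint(np.array([[0.5, 0.0, 1.0]]), line)

    def test_matches_ray_casting_oracle(self):
        rng = np.random.default_rng(123)
        coords = random_star_polygon(rng)
        poly = Polygon(coords)
        assert poly.is_valid
        pts = rng.uniform(-6, 6, size=(1000, 2))
        cloud = np.column_stack([pts, np.zeros(1000)])
        kept = bp.points_in_footprint(cloud, poly)
        kept_xy = {tuple(p[:2]) for p in kept}
        oracle = {tuple(p) for p in pts if ray_casting_contains(coords, *p)}
        assert kept_xy == oracle


# --- estimate_height --------------------------------------------------------

class TestEstimateHeight:
    @pytest.mark.parametrize("zs,expected", [([1, 2, 3], 2.0), ([1, 2, 3, 4], 2.5)])
    def test_median_conventions(self, zs, expected):
        assert bp.estimate_height(zs) == expected

    def test_empty_errors(self):
        with pytest.raises(ExtrusionError, match="no points"):
            bp.estimate_height([])

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(7)
        zs = rng.normal(10, 3, 1001)
        assert bp.estimate_height(zs) == sorted(zs)[500]


# --- estimate_base ----------------------------------------------------------

class TestEstimateBase:
    def _ring_cloud(self, z, n=200, seed=0):
        rng = np.random.default_rng(seed)
        # scatter around, but not inside, the unit square
        pts = []
        while len(pts) < n:
            x, y = rng.uniform(-1.5, 2.5, 2)
            if not (0 < x < 1 and 0 < y < 1):
                pts.append((x, y, z if np.isscalar(z) else z(x, y)))
        return np.array(pts)

    def test_flat_ground(self):
        cloud = self._ring_cloud(0.0)
        assert bp.estimate_base(cloud, box(0, 0, 1, 1), 2.0) == 0.0

    def test_offset_ground(self):
        cloud = self._ring_cloud(3.2)
        assert bp.estimate_base(cloud, box(0, 0, 1, 1), 2.0) == pytest.approx(3.2)

    def test_no_annulus_points_errors(self):
        with pytest.raises(ExtrusionError, match="widen the buffer"):
            bp.estimate_base(np.array([[50.0, 50.0, 0.0]]), box(0, 0, 1, 1), 2.0)

    def test_sloped_ground_matches_geometric_oracle(self):
        w = 2.0
        cloud = self._ring_cloud(lambda x, y: 0.5 * x + 0.1 * y, n=500, seed=4)
        rect = box(0, 0, 1, 1)

        def dist_to_rect(x, y):
            dx = max(0 - x, 0.0, x - 1)
            dy = max(0 - y, 0.0, y - 1)
            return np.hypot(dx, dy)

        # avoid points within the buffer-arc discretisation band
        dists = np.array([dist_to_rect(x, y) for x, y, _ in cloud])
        keep = np.abs(dists - w) > 0.02
        cloud = cloud[keep]
        oracle_zs = [z for (x, y, z), d in zip(cloud, dists[keep]) if d <= w]
        assert bp.estimate_base(cloud, rect, w) == pytest.approx(
            np.median(oracle_zs), abs=1e-12)


# --- extrude / polygon_area -------------------------------------------------

class TestExtrude:
    def test_simple_volume(self):
        m = bp.extrude(100.0, 0.0, 6.0)
        assert m.height == 6.0 and m.volume == 600.0

    def test_base_invariance_of_height(self):
        m = bp.extrude(100.0, 3.2, 9.2)
        assert m.volume == pytest.approx(600.0)

    def test_top_below_base_errors(self):
        with pytest.raises(ExtrusionError, match="unreconstructable"):
            bp.extrude(100.0, 5.0, 5.0)

    @given(st.floats(0.1, 1e4), st.floats(-100, 100), st.floats(0.1, 500))
    @settings(max_examples=50, deadline=None)
    def test_affine_in_height(self, area, base, height):
        one = bp.extrude(area, base, base + height)
        two = bp.extrude(area, base, base + 2 * height)
        assert two.volume == pytest.approx(2 * one.volume, rel=1e-12)


class TestPolygonArea:
    def test_unit_square(self):
        assert bp.polygon_area(box(0, 0, 1, 1)) == 1.0

    def test_triangle(self):
        assert bp.polygon_area([(0, 0), (1, 0), (0, 1)]) == pytest.approx(0.5)

    def test_orientation_independent(self):
        cw = [(0, 0), (0, 1), (1, 1), (1, 0)]
        ccw = list(reversed(cw))
        assert bp.polygon_area(cw) == bp.polygon_area(ccw) == 1.0

    def test_too_few_vertices(self):
        with pytest.raises(ExtrusionError):
            bp.polygon_area([(0, 0), (1, 0)])

    def test_convex_polygon_matches_triangulation_oracle(self):
        rng = np.random.default_rng(11)
        pts = rng.uniform(0, 10, size=(12, 2))
        from shapely.geometry import MultiPoint
        hull = MultiPoint([tuple(p) for p in pts]).convex_hull
        coords = list(hull.exterior.coords)[:-1]
        assert bp.polygon_area(coords) == pytest.approx(
            triangulation_fan_area(coords), rel=1e-9)

    def test_star_polygon_matches_shoelace_oracle(self):
        rng = np.random.default_rng(5)
        coords = random_star_polygon(rng, n=11)
        shoelace = abs(sum(x1 * y2 - x2 * y1 for (x1, y1), (x2, y2) in
                           zip(coords, coords[1:] + coords[:1]))) / 2
        assert bp.polygon_area(coords) == pytest.approx(shoelace, rel=1e-9)


# --- pipeline-level ---------------------------------------------------------

class TestExtrudeBuildings:
    def test_noiseless_world_recovers_heights_exactly(self, rect_building):
        b1 = rect_building("b1", "n", 0, 0, 10, 8, height=6.0, base=2.0)
        b2 = rect_building("b2", "n", 30, 0, 12, 10, height=15.0, base=2.0)
        cfg = bp.SimConfig(seed=0, point_noise_sd=0.0, point_density=2.0)
        cloud = bp.generate_point_cloud([b1, b2], cfg)
        models = bp.extrude_buildings([b1, b2], cloud)
        for b in (b1, b2):
            assert models[b.id].height == pytest.approx(b.height, abs=1e-12)
            assert models[b.id].volume == pytest.approx(
                b.footprint_area * b.height, rel=1e-12)

    def test_zero_point_building_dropped_with_warning(self, rect_building, caplog):
        far = rect_building("lonely", "n", 1000, 1000, 10, 10)
        near = rect_building("ok", "n", 0, 0, 10, 10, base=0.0)
        cfg = bp.SimConfig(seed=1, point_noise_sd=0.0, point_density=2.0)
        cloud = bp.generate_point_cloud([near], cfg)
        with caplog.at_level("WARNING"):
            models = bp.extrude_buildings([near, far], cloud)
        assert "lonely" not in models and "ok" in models
        assert any("lonely" in r.message for r in caplog.records)

    def test_base_override_wins(self, rect_building):
        b = rect_building("b", "n", 0, 0, 10, 10, height=6.0, base=5.0)
        cfg = bp.SimConfig(seed=2, point_noise_sd=0.0, point_density=2.0)
        cloud = bp.generate_point_cloud([b], cfg)
        models = bp.extrude_buildings([b], cloud, base_overrides={"b": 1.0})
        # top is at 11 m; with the overridden base the height becomes 10 m
        assert models["b"].height == pytest.approx(10.0, abs=1e-12)
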