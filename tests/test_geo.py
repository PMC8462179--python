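"""Least-cost sea distances, shore distances, MCP, availability region, sampling."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Point, Polygon, box

import sealforage as sf
from sealforage.geo import equal_area_project, haversine_km


@pytest.fixture(scope="module")
def graph(small_seascape):
    return sf.SeaGraph(small_seascape)


def _networkx_distances(seascape, origin_node):
    """Independent Dijkstra oracle over the same sea lattice."""
    import networkx as nx

    ny, nx_ = seascape.shape
    G = nx.Graph()
    sea = seascape.sea
    for r in range(ny):
        for c in range(nx_):
            if not sea[r, c]:
                continue
            for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < ny and 0 <= c2 < nx_ and sea[r2, c2]:
                    w = seascape.cell_km * (np.sqrt(2) if dr and dc else 1.0)
                    G.add_edge((r, c), (r2, c2), weight=w)
    return nx.single_source_dijkstra_path_length(G, origin_node)


class TestLeastCost:
    def test_zero_to_self(self, small_seascape, graph):
        h = small_seascape.haulouts.iloc[0]
        d = sf.least_cost_distance((h.x, h.y), [(h.x, h.y)], graph)
        assert d[0] == 0.0

    def test_open_water_within_discretization_bound(self, small_seascape, graph):
        # two offshore points with no land between
        a = (40.0, 20.0)
        b = (52.0, 40.0)
        assert small_seascape.is_sea_xy(*map(np.atleast_1d, a)).all()
        d = sf.least_cost_distance(a, [b], graph)[0]
        direct = np.hypot(b[0] - a[0], b[1] - a[1])
        assert direct - small_seascape.cell_km * np.sqrt(2) <= d <= 1.083 * direct + 2 * small_seascape.cell_km

    def test_matches_networkx_dijkstra(self, small_seascape, graph):
        """Exact agreement with an independent shortest-path implementation."""
        sea_rc = np.argwhere(small_seascape.sea)
        r0, c0 = sea_rc[len(sea_rc) // 2]
        oracle = _networkx_distances(small_seascape, (int(r0), int(c0)))
        node = graph.node_of_cell[r0 * small_seascape.shape[1] + c0]
        mine = graph.distance_grid(graph.distances_from(int(node)))
        rng = np.random.default_rng(0)
        for r, c in sea_rc[rng.choice(len(sea_rc), 80, replace=False)]:
            assert mine[r, c] == pytest.approx(oracle[(int(r), int(c))], abs=1e-9)

    def test_triangle_inequality_and_lower_bound(self, small_seascape, graph):
        rng = np.random.default_rng(1)
        sea_rc = np.argwhere(small_seascape.sea)
        cell = small_seascape.cell_km
        pts = [(c[1] * cell + cell / 2, c[0] * cell + cell / 2)
               for c in sea_rc[rng.choice(len(sea_rc), 9, replace=False)]]
        D = np.array([sf.least_cost_distance(p, pts, graph) for p in pts])
        for i in range(9):
            for j in range(9):
                direct = np.hypot(pts[i][0] - pts[j][0], pts[i][1] - pts[j][1])
                assert D[i, j] >= direct - 1e-9          # never below straight line
                for k in range(9):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-9

    def test_origin_on_land_rejected(self, small_seascape, graph):
        # deep inland cell: beyond 1-cell snap tolerance
        rc = np.argwhere(small_seascape.land)
        from scipy import ndimage
        inner = ndimage.binary_erosion(small_seascape.land, np.ones((5, 5), bool))
        r, c = np.argwhere(inner)[0]
        cell = small_seascape.cell_km
        with pytest.raises(ValueError, match="land"):
            sf.least_cost_distance((c * cell + 1, r * cell + 1), [(40, 20)], graph)


class TestDistanceToShore:
    coast = LineString([(0, 0), (0, 100)])

    def test_point_on_coast_zero(self):
        assert sf.distance_to_shore([(0.0, 50.0)], self.coast)[0] == 0.0

    def test_offshore_point(self):
        assert sf.distance_to_shore([(10.0, 50.0)], self.coast)[0] == pytest.approx(10.0)

    def test_matches_dense_vertex_scan(self):
        rng = np.random.default_rng(5)
        wiggly = LineString(np.column_stack([np.sin(np.linspace(0, 6, 400)) * 5,
                                             np.linspace(0, 100, 400)]))
        pts = np.column_stack([rng.uniform(5, 40, 25), rng.uniform(0, 100, 25)])
        got = sf.distance_to_shore(pts, wiggly)
        # oracle: exhaustive scan over densely resampled coastline vertices
        dense = [wiggly.interpolate(f, normalized=True) for f in np.linspace(0, 1, 20000)]
        dx = np.array([p.x for p in dense])
        dy = np.array([p.y for p in dense])
        for i, (x, y) in enumerate(pts):
            d = np.min(np.hypot(dx - x, dy - y))
            assert got[i] == pytest.approx(d, abs=1e-3)

    def test_empty_coastline_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sf.distance_to_shore([(0, 0)], LineString())


class TestExtractCovariates:
    def test_cell_center_lookup(self, small_seascape, graph):
        sc = small_seascape
        r, c = np.argwhere(sc.sea)[50]
        x = c * sc.cell_km + sc.cell_km / 2
        y = r * sc.cell_km + sc.cell_km / 2
        out = sf.extract_covariates(pd.DataFrame({"x": [x], "y": [y]}), sc, graph)
        assert out["bathy"].iloc[0] == pytest.approx(sc.bathy[r, c])
        assert out["sediment"].iloc[0] == sc.sediment[r, c]
        assert out["tidal"].iloc[0] == pytest.approx(sc.tidal[r, c])

    def test_out_of_extent_dropped(self, small_seascape, graph):
        pts = pd.DataFrame({"x": [40.0, -50.0], "y": [20.0, 20.0]})
        out = sf.extract_covariates(pts, small_seascape, graph)
        assert len(out) == 1

    def test_batch_equals_per_point(self, small_seascape, graph):
        rng = np.random.default_rng(2)
        sea_rc = np.argwhere(small_seascape.sea)
        cell = small_seascape.cell_km
        pick = sea_rc[rng.choice(len(sea_rc), 12, replace=False)]
        pts = pd.DataFrame({"x": pick[:, 1] * cell + cell / 2,
                            "y": pick[:, 0] * cell + cell / 2})
        batch = sf.extract_covariates(pts, small_seascape, graph)
        singles = pd.concat([
            sf.extract_covariates(pts.iloc[[i]], small_seascape, graph)
            for i in range(len(pts))], ignore_index=True)
        pd.testing.assert_frame_equal(batch.reset_index(drop=True), singles)


class TestMCP:
    def test_unit_square(self):
        poly = sf.mcp([(0, 0), (1, 0), (1, 1), (0, 1)])
        assert poly.area == pytest.approx(1.0)

    def test_hull_contains_all_points(self):
        rng = np.random.default_rng(11)
        pts = rng.uniform(0, 50, size=(60, 2))
        poly = sf.mcp(pts)
        assert all(poly.buffer(1e-9).contains(Point(x, y)) for x, y in pts)
        hull_xy = set(map(tuple, np.round(np.asarray(poly.exterior.coords), 9)))
        pts_set = set(map(tuple, np.round(pts, 9)))
        assert hull_xy <= pts_set

    def test_area_matches_gift_wrap_shoelace(self):
        """Independent oracle: gift-wrapping hull + shoelace area."""
        rng = np.random.default_rng(13)
        pts = rng.uniform(-30, 30, size=(80, 2))

        def gift_wrap(P):
            P = [tuple(p) for p in P]
            start = min(P)
            hull, point = [], start
            while True:
                hull.append(point)
                cand = P[0] if P[0] != point else P[1]
                for q in P:
                    if q == point:
                        continue
                    cross = ((cand[0] - point[0]) * (q[1] - point[1])
                             - (cand[1] - point[1]) * (q[0] - point[0]))
                    if cross < 0 or (cross == 0 and
                                     np.hypot(q[0] - point[0], q[1] - point[1])
                                     > np.hypot(cand[0] - point[0], cand[1] - point[1])):
                        cand = q
                point = cand
                if point == start:
                    return hull

        hull = gift_wrap(pts)
        x = np.array([p[0] for p in hull])
        y = np.array([p[1] for p in hull])
        area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        assert sf.mcp(pts).area == pytest.approx(area, abs=1e-9)

    def test_collinear_rejected(self):
        with pytest.raises(ValueError):
            sf.mcp([(0, 0), (1, 1), (2, 2)])


class TestAvailabilityRegion:
    mcp_poly = Polygon([(0, 0), (20, 0), (20, 10), (0, 10)])

    def test_area_ratio_three(self):
        region = sf.availability_region(self.mcp_poly, shelf=box(-100, -100, 100, 100))
        assert region.scaled.area / region.mcp.area == pytest.approx(3.0, rel=1e-3)

    def test_full_shelf_clip_is_scaled_minus_land(self):
        land = box(-5, -5, 3, 3)
        region = sf.availability_region(self.mcp_poly, shelf=box(-100, -100, 100, 100),
                                        land=land)
        expect = region.scaled.difference(land)
        assert region.clipped.area == pytest.approx(expect.area, rel=1e-9)

    def test_half_plane_clip_matches_monte_carlo(self):
        """Clipped area vs Monte-Carlo integration of the same region."""
        shelf = box(-1000, -1000, 10.0, 1000)    # half-plane x <= 10
        region = sf.availability_region(self.mcp_poly, shelf=shelf)
        rng = np.random.default_rng(21)
        minx, miny, maxx, maxy = region.scaled.bounds
        n = 10**6
        xs = rng.uniform(minx, maxx, n)
        ys = rng.uniform(miny, maxy, n)
        from shapely import contains_xy
        p_hat = contains_xy(region.clipped, xs, ys).mean()
        box_area = (maxx - minx) * (maxy - miny)
        est = p_hat * box_area
        se = box_area * np.sqrt(p_hat * (1 - p_hat) / n)
        assert abs(region.clipped.area - est) <= 3 * se

    def test_clipped_subset_of_scaled(self):
        region = sf.availability_region(self.mcp_poly, shelf=box(0, 0, 12, 8))
        assert region.clipped.within(region.scaled.buffer(1e-9))

    def test_empty_clip_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sf.availability_region(self.mcp_poly, shelf=box(500, 500, 600, 600))


class TestPseudoAbsences:
    region = sf.availability_region(Polygon([(0, 0), (40, 0), (40, 20), (0, 20)]),
                                    shelf=box(-100, -100, 100, 100))

    def test_two_per_dive_per_individual(self):
        counts = {"a": 500, "b": 40}
        pts = sf.sample_pseudo_absences(self.region, counts, seed=1)
        got = pts.groupby("individual").size()
        assert got["a"] == 1000 and got["b"] == 80

    def test_all_inside_clipped_polygon(self):
        pts = sf.sample_pseudo_absences(self.region, {"a": 300}, seed=2)
        from shapely import contains_xy
        assert contains_xy(self.region.clipped,
                           pts["x"].to_numpy(), pts["y"].to_numpy()).all()

    def test_uniform_over_rectangle(self):
        """Chi-square GOF against uniform over equal-area sub-cells."""
        from scipy import stats
        region = sf.availability_region(Polygon([(0, 0), (60, 0), (60, 30), (0, 30)]),
                                        shelf=box(-500, -500, 500, 500))
        pts = sf.sample_pseudo_absences(region, {"a": 10000}, seed=3)
        minx, miny, maxx, maxy = region.clipped.bounds
        H, _, _ = np.histogram2d(pts["x"], pts["y"], bins=[8, 4],
                                 range=[[minx, maxx], [miny, maxy]])
        res = stats.chisquare(H.ravel())
        assert res.pvalue > 0.01

    def test_determinism(self):
        a = sf.sample_pseudo_absences(self.region, {"a": 100}, seed=9)
        b = sf.sample_pseudo_absences(self.region, {"a": 100}, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_sliver_region_rejected(self):
        # diagonal hair-thin strip: almost no area within its own bounding box
        sliver = sf.AvailabilityRegion(
            mcp=box(0, 0, 1, 1), scaled=box(0, 0, 1, 1),
            clipped=Polygon([(0, 0), (1000, 100), (1000, 100.0001), (0, 0.0001)]))
        with pytest.raises(ValueError, match="acceptance"):
            sf.sample_pseudo_absences(sliver, {"a": 50}, seed=0)


class TestGeographicMode:
    def test_haversine_equator_degree(self):
        d = haversine_km(0.0, 0.0, 1.0, 0.0)
        assert d == pytest.approx(111.19, abs=0.1)

    def test_equal_area_projection_preserves_area(self):
        # 1-degree cell at 48N: area ~ 111.19^2 * cos(48)
        lons = np.array([0.0, 1.0, 1.0, 0.0])
        lats = np.array([47.5, 47.5, 48.5, 48.5])
        x, y = equal_area_project(lons, lats, 0.5, 48.0)
        poly = Polygon(zip(x, y))
        expect = 111.19**2 * np.cos(np.radians(48.0))
        assert poly.area == pytest.approx(expect, rel=0.01)

    def test_mcp_geographic_mode(self):
        lon = np.array([0.0, 0.5, 0.5, 0.0, 0.25])
        lat = np.array([48.0, 48.0, 48.3, 48.3, 48.15])
        poly = sf.mcp(np.column_stack([lon, lat]), mode="geographic")
        expect = (0.5 * 111.19 * np.cos(np.radians(48.15))) * (0.3 * 111.19)
        assert poly.area == pytest.approx(expect, rel=0.02)
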