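import itertools

import numpy as np
import pytest
from shapely import box
from shapely.geometry import LineString, Point

from forestscape.gridding import GridCell, build_grid
from forestscape.road_metrics import RoadNetwork, dnr, non_mnd, planarize, srl


def make_cell(x0=0.0, y0=0.0, size=5_000.0, cid=0) -> GridCell:
    return GridCell(cid, 0, 0, box(x0, y0, x0 + size, y0 + size), 1.0)


class TestPlanarize:
    def test_single_crossing(self):
        """Two crossing segments -> one degree-4 junction and four terminals."""
        g = planarize([
            LineString([(0, -1), (0, 1)]),
            LineString([(-1, 0), (1, 0)]),
        ])
        degrees = sorted(d for _, d in g.degree())
        assert degrees == [1, 1, 1, 1, 4]

    def test_single_segment(self):
        g = planarize([LineString([(0, 0), (5, 5)])])
        assert sorted(d for _, d in g.degree()) == [1, 1]

    def test_degree2_vertices_dissolved(self):
        """A polyline drawn in two collinear pieces becomes one edge."""
        g = planarize([
            LineString([(0, 0), (1, 0)]),
            LineString([(1, 0), (2, 0)]),
        ])
        assert g.number_of_nodes() == 2
        assert g.number_of_edges() == 1

    def test_duplicate_segments_deduplicated(self):
        seg = LineString([(0, 0), (1, 1)])
        g = planarize([seg, LineString([(0, 0), (1, 1)])])
        assert g.number_of_edges() == 1

    def test_zero_length_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero-length"):
            g = planarize([LineString([(0, 0), (0, 0)]), LineString([(0, 0), (1, 0)])])
        assert g.number_of_edges() == 1

    def test_random_network_matches_allpairs_oracle(self):
        """Node/degree multiset equals an O(n^2) crossing enumeration."""
        rng = np.random.default_rng(11)
        segs = [
            LineString([rng.uniform(0, 100, 2), rng.uniform(0, 100, 2)])
            for _ in range(50)
        ]
        g = planarize(segs)
        # oracle: collect endpoints and all pairwise interior crossings
        events: dict[tuple[float, float], int] = {}

        def snap(p):
            return (round(p[0], 6), round(p[1], 6))

        def bump(p, inc):
            events[snap(p)] = events.get(snap(p), 0) + inc

        for s in segs:
            bump(s.coords[0], 1)
            bump(s.coords[-1], 1)
        for a, b in itertools.combinations(segs, 2):
            inter = a.intersection(b)
            if inter.is_empty:
                continue
            pts = [inter] if isinstance(inter, Point) else list(getattr(inter, "geoms", []))
            for p in pts:
                if isinstance(p, Point):
                    # a crossing adds two passes (degree 4) unless it is an endpoint
                    for s in (a, b):
                        at_end = p.equals_exact(Point(s.coords[0]), 1e-9) or \
                            p.equals_exact(Point(s.coords[-1]), 1e-9)
                        if not at_end:
                            bump((p.x, p.y), 2)
        oracle_degrees = sorted(v for v in events.values())
        got_degrees = sorted(d for _, d in g.degree())
        assert got_degrees == oracle_degrees


class TestMetrics:
    def test_srl_whole_segment_inside(self):
        cell = make_cell()
        seg = LineString([(1_000, 1_000), (3_000, 1_000)])  # 2 km in a 25 km^2 cell
        assert srl(cell, [seg]) == pytest.approx(0.08)

    def test_srl_clips_at_boundary(self):
        cell = make_cell()
        seg = LineString([(-2_500, 2_500), (7_500, 2_500)])  # 10 km bisecting midline
        assert srl(cell, [seg]) == pytest.approx(0.2)

    def test_srl_random_matches_per_segment_oracle(self):
        rng = np.random.default_rng(5)
        cell = make_cell()
        segs = [
            LineString([rng.uniform(-2_000, 7_000, 2), rng.uniform(-2_000, 7_000, 2)])
            for _ in range(40)
        ]
        expected = sum(s.intersection(cell.geometry).length for s in segs) / 1e3 / 25.0
        assert srl(cell, segs) == pytest.approx(expected, rel=1e-12)

    def test_dnr_centroid_on_road(self):
        cell = make_cell()
        road = LineString([(0, 2_500), (5_000, 2_500)])  # passes through centroid
        assert dnr(cell, [road]) == pytest.approx(0.0)

    def test_dnr_edge_road(self):
        cell = make_cell()
        road = LineString([(0, 0), (5_000, 0)])  # along the southern edge
        assert dnr(cell, [road]) == pytest.approx(2.5)

    def test_dnr_empty_network_is_missing(self):
        assert np.isnan(dnr(make_cell(), []))

    def test_dnr_matches_densified_bruteforce(self):
        rng = np.random.default_rng(9)
        cell = make_cell()
        segs = [
            LineString([rng.uniform(-10_000, 15_000, 2), rng.uniform(-10_000, 15_000, 2)])
            for _ in range(25)
        ]
        got = dnr(cell, segs)
        c = np.array([cell.centroid.x, cell.centroid.y])
        t = np.linspace(0.0, 1.0, 200_001)[:, None]
        best = np.inf
        for s in segs:
            a = np.array(s.coords[0])
            b = np.array(s.coords[-1])
            pts = a + t * (b - a)
            best = min(best, np.hypot(*(pts - c).T).min())
        assert got == pytest.approx(best / 1e3, abs=1e-6)

    def test_non_mnd_empty_cell(self):
        g = planarize([])
        assert non_mnd(make_cell(), g) == (0.0, 0.0)

    def test_non_mnd_crossing_fixture(self):
        """One interior crossing: NON 5/25; MND 1.6 plain, 0.064 per-area."""
        cell = make_cell()
        g = planarize([
            LineString([(2_500, 1_000), (2_500, 4_000)]),
            LineString([(1_000, 2_500), (4_000, 2_500)]),
        ])
        non_val, mnd_val = non_mnd(cell, g, mnd_per_area=False)
        assert non_val == pytest.approx(0.2)
        assert mnd_val == pytest.approx(1.6)
        _, mnd_area = non_mnd(cell, g, mnd_per_area=True)
        assert mnd_area == pytest.approx(1.6 / 25.0)

    def test_node_on_edge_counted_once(self):
        """A node on a shared cell edge belongs to exactly one cell."""
        grid = build_grid(box(0, 0, 10_000, 10_000), 5_000)
        g = planarize([LineString([(5_000, 2_500), (6_000, 2_500)])])
        counts = [non_mnd(c, g)[0] for c in grid.cells]
        # terminal at x=5000 sits on the boundary between cols 0 and 1
        assert sum(1 for v in counts if v > 0) >= 1
        total_nodes = sum(v * 25.0 for v in counts)
        assert total_nodes == pytest.approx(2.0)


class TestNetworkTable:
    def test_conservation_and_monotonicity(self, small_dataset):
        """SRL*area sums to the clipped network length; nested networks give
        period-monotone SRL/NON and non-increasing DNR for the main class."""
        from forestscape.road_metrics import metrics_table

        grid = small_dataset.grid
        networks = small_dataset.networks
        table = metrics_table(grid, networks)
        area_km2 = grid.cell_area / 1e6
        for period, net in networks.items():
            segs = net.for_class("main")
            clipped = sum(
                s.intersection(c.geometry).length
                for s in segs for c in grid.cells
            ) / 1e3
            got = table.xs(period, level="period")["SRL_main"].sum() * area_km2
            assert got == pytest.approx(clipped, rel=1e-9)
        periods = list(networks)
        for a, b in zip(periods, periods[1:]):
            ta = table.xs(a, level="period")
            tb = table.xs(b, level="period")
            assert (tb["SRL_main"] >= ta["SRL_main"] - 1e-12).all()
            assert (tb["NON_main"] >= ta["NON_main"] - 1e-12).all()
            assert (tb["DNR_main"] <= ta["DNR_main"] + 1e-12).all()

    def test_road_class_vocabulary_enforced(self):
        with pytest.raises(ValueError, match="unknown road class"):
            RoadNetwork("p1", [LineString([(0, 0), (1, 1)])], ["tertiary"])

    def test_geojson_round_trip(self, tmp_path, small_dataset):
        net = small_dataset.networks["p2"]
        path = tmp_path / "roads.geojson"
        net.to_geojson(path)
        back = RoadNetwork.from_geojson(path, period="p2")
        assert back.classes == net.classes
        assert len(back.segments) == len(net.segments)
        assert back.total_length() == pytest.approx(net.total_length())
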