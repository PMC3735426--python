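import math

import numpy as np
import pytest

import streetmorph as sm
from streetmorph.street_graph import StreetGraphError, polyline_length

from _oracles import cluster_endpoints_brute, metric_distances_brute, random_graph_lines


class TestBuild:
    def test_exact_touch_shares_node(self):
        g = sm.build_segment_graph(
            [[(1000, 0), (1100, 0)], [(1100, 0), (1100, 100)]]
        )
        assert len(g) == 2
        assert len(g.node_coords) == 3
        shared = [n for n, inc in g.node_incidence.items() if len(inc) == 2]
        assert len(shared) == 1

    def test_snap_merges_nearby_endpoints(self):
        g = sm.build_segment_graph(
            [[(1000, 0), (1100, 0)], [(1100.5, 0), (1200, 0)]], snap_tolerance=1.0
        )
        assert len(g.node_coords) == 3
        assert g.connected()

    def test_no_snap_leaves_gap(self):
        g = sm.build_segment_graph(
            [[(1000, 0), (1100, 0)], [(1100.5, 0), (1200, 0)]], snap_tolerance=0.1
        )
        assert len(g.node_coords) == 4
        assert not g.connected()

    def test_empty_input_rejected(self):
        with pytest.raises(StreetGraphError, match="no segments"):
            sm.build_segment_graph([])

    def test_geographic_coordinates_rejected(self):
        with pytest.raises(StreetGraphError, match="project"):
            sm.build_segment_graph([[(-3.2, 51.6), (-3.1, 51.6)]])

    def test_loop_rejected_by_default(self):
        loop = [[(1000, 0), (1100, 0), (1100, 100), (1000, 0)]]
        with pytest.raises(StreetGraphError, match="loop"):
            sm.build_segment_graph(loop)
        g = sm.build_segment_graph(loop, allow_loops=True)
        assert len(g) == 1

    def test_multi_edge_rejected_by_default(self):
        lines = [
            [(1000, 0), (1100, 0)],
            [(1000, 0), (1050, 30), (1100, 0)],
        ]
        with pytest.raises(StreetGraphError, match="multi-edge"):
            sm.build_segment_graph(lines)
        g = sm.build_segment_graph(lines, allow_multi_edges=True)
        assert len(g) == 2

    def test_exact_duplicates_dropped(self):
        g = sm.build_segment_graph(
            [[(1000, 0), (1100, 0)], [(1100, 0), (1000, 0)]]
        )
        assert len(g) == 1

    def test_perturbed_grid_matches_brute_force_clustering(self):
        rng = np.random.default_rng(42)
        tol = 1.0
        base = {}
        for j in range(4):
            for i in range(4):
                base[(i, j)] = (1000.0 + 150 * i, 200.0 + 150 * j)
        lines = []
        endpoints = []
        for (i, j), p in base.items():
            for q in ((i + 1, j), (i, j + 1)):
                if q in base:
                    a = (p[0] + rng.uniform(-0.3, 0.3), p[1] + rng.uniform(-0.3, 0.3))
                    b = (
                        base[q][0] + rng.uniform(-0.3, 0.3),
                        base[q][1] + rng.uniform(-0.3, 0.3),
                    )
                    lines.append([a, b])
                    endpoints += [a, b]
        g = sm.build_segment_graph(lines, snap_tolerance=tol)
        groups = cluster_endpoints_brute(np.asarray(endpoints), tol)
        assert len(g.node_coords) == len(groups)
        degrees = sorted(len(inc) for inc in g.node_incidence.values())
        assert degrees == sorted(len(grp) for grp in groups)

    def test_rebuild_is_idempotent(self):
        rng = np.random.default_rng(3)
        lines = random_graph_lines(rng, 10)
        g1 = sm.build_segment_graph(lines)
        g2 = sm.build_segment_graph([s.polyline for s in g1.segments.values()])
        assert len(g1) == len(g2)
        assert sorted(len(i) for i in g1.node_incidence.values()) == sorted(
            len(i) for i in g2.node_incidence.values()
        )
        assert math.isclose(
            sum(s.length for s in g1.segments.values()),
            sum(s.length for s in g2.segments.values()),
        )

    def test_collinear_merge_fuses_straight_chain(self):
        lines = [[(1000.0 + 100 * i, 0.0), (1100.0 + 100 * i, 0.0)] for i in range(3)]
        lines.append([(1300.0, 0.0), (1300.0, 100.0)])
        g = sm.build_segment_graph(lines, merge_collinear=True)
        assert len(g) == 2
        assert math.isclose(max(s.length for s in g.segments.values()), 300.0)


class TestTurnCost:
    def _shared_node(self, g, a, b):
        return g.shared_nodes(a, b)[0]

    def test_collinear_is_zero(self, chain_graph):
        n = self._shared_node(chain_graph, 0, 1)
        assert chain_graph.turn_cost(0, 1, n) == pytest.approx(0.0, abs=1e-12)

    def test_perpendicular_is_ninety(self):
        g = sm.build_segment_graph([[(1000, 0), (1100, 0)], [(1100, 0), (1100, 50)]])
        n = self._shared_node(g, 0, 1)
        assert g.turn_cost(0, 1, n) == pytest.approx(90.0)

    def test_135_interior_angle_is_45(self):
        # segments (0,0)->(100,0) and (100,0)->(200,100)... 45 deg deviation
        g = sm.build_segment_graph(
            [[(1000, 0), (1100, 0)], [(1100, 0), (1200, 100)]]
        )
        n = self._shared_node(g, 0, 1)
        assert g.turn_cost(0, 1, n) == pytest.approx(45.0)

    def test_symmetric_in_segments(self, plus_graph):
        g = plus_graph
        for a in g.segments:
            for b in g.segments:
                if a == b:
                    continue
                for n in g.shared_nodes(a, b):
                    assert g.turn_cost(a, b, n) == pytest.approx(g.turn_cost(b, a, n))

    def test_invariant_under_vertex_reversal(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            p0, p1, p2 = (rng.uniform(0, 500, 2) + 1000 for _ in range(3))
            g = sm.build_segment_graph([[tuple(p0), tuple(p1)], [tuple(p1), tuple(p2)]])
            gr = sm.build_segment_graph(
                [[tuple(p1), tuple(p0)], [tuple(p2), tuple(p1)]]
            )
            n = self._shared_node(g, 0, 1)
            nr = self._shared_node(gr, 0, 1)
            assert g.turn_cost(0, 1, n) == pytest.approx(gr.turn_cost(0, 1, nr))

    def test_not_incident_errors(self, chain_graph):
        far_node = [
            n for n in chain_graph.node_coords
            if not {0} & chain_graph.node_incidence[n]
        ][0]
        with pytest.raises(StreetGraphError, match="not incident"):
            chain_graph.turn_cost(0, 1, far_node)


class TestNetworkDistance:
    def test_adjacent_chain_half_plus_half(self, chain_graph):
        assert sm.network_distance(chain_graph, 0, 1) == pytest.approx(100.0)

    def test_identity_zero(self, chain_graph):
        assert sm.network_distance(chain_graph, 2, 2) == 0.0

    def test_disconnected_inf(self):
        g = sm.build_segment_graph(
            [[(1000, 0), (1100, 0)], [(5000, 0), (5100, 0)]]
        )
        assert sm.network_distance(g, 0, 1) == math.inf

    def test_all_pairs_match_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            g = sm.build_segment_graph(random_graph_lines(rng, 8))
            brute = metric_distances_brute(g)
            for i in g.segments:
                dists = sm.network_distances_from(g, i)
                for j in g.segments:
                    assert dists[j] == pytest.approx(brute[(i, j)], rel=1e-9)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(21)
        g = sm.build_segment_graph(random_graph_lines(rng, 10))
        sids = list(g.segments)
        dist = {i: sm.network_distances_from(g, i) for i in sids}
        for _ in range(200):
            a, b, c = rng.choice(sids, 3)
            if math.inf in (dist[a][b], dist[b][c], dist[a][c]):
                continue
            assert dist[a][c] <= dist[a][b] + dist[b][c] + 1e-6


class TestIO:
    def test_csv_round_trip(self, tmp_path, chain_graph):
        seg_csv = tmp_path / "segments.csv"
        turn_csv = tmp_path / "turns.csv"
        chain_graph.to_csv(seg_csv, turn_csv)
        g2 = sm.SegmentGraph.from_csv(seg_csv)
        assert set(g2.segments) == set(chain_graph.segments)
        for sid, seg in chain_graph.segments.items():
            assert g2.segments[sid].polyline == seg.polyline
            assert g2.segments[sid].length == pytest.approx(seg.length)
            assert g2.segments[sid].end_nodes == seg.end_nodes

    def test_geojson_centerline_reader(self, tmp_path):
        import json

        path = tmp_path / "streets.geojson"
        gj = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {},
                    "geometry": {
                        "type": "LineString",
                        "coordinates": [[1000, 0], [1100, 0]],
                    },
                },
                {
                    "type": "Feature",
                    "properties": {},
                    "geometry": {
                        "type": "MultiLineString",
                        "coordinates": [[[1100, 0], [1100, 100]]],
                    },
                },
            ],
        }
        path.write_text(json.dumps(gj))
        lines = sm.read_centerlines_geojson(path)
        assert len(lines) == 2
        g = sm.build_segment_graph(lines)
        assert len(g) == 2


def test_segment_length_matches_polyline():
    poly = [(1000, 0), (1100, 0), (1100, 100)]
    assert polyline_length(poly) == pytest.approx(200.0)
    g = sm.build_segment_graph([poly])
    assert next(iter(g.segments.values())).length == pytest.approx(200.0)
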