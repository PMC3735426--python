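"""Street-segment graph construction.

A street network is modelled as a collection of polyline *segments* joined at
shared endpoint *nodes*.  Every space-syntax quantity downstream (connectivity,
angular least-cost paths, movement potential) is defined on this graph, so the
construction here is deliberately deterministic: endpoints within a snap
tolerance are merged, zero-length and duplicate segments are dropped, and loops
or parallel edges are rejected unless explicitly allowed.

Coordinates must be planar and in metres.  Inputs whose bounding box fits
inside [-180, 180] x [-90, 90] are assumed to be geographic (degrees) and are
rejected with a pointer to reprojection.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Dict, Hashable, Iterable, List, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import LineString, shape
from shapely import wkt as shapely_wkt

Point = Tuple[float, float]

DEFAULT_SNAP_TOLERANCE = 0.1  # metres


class StreetGraphError(ValueError):
    """Raised for invalid street-network inputs."""


def polyline_length(vertices: Sequence[Point]) -> float:
    """Sum of consecutive vertex distances of a polyline, in metres."""
    arr = np.asarray(vertices, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        return 0.0
    return float(np.sqrt(((arr[1:] - arr[:-1]) ** 2).sum(axis=1)).sum())


@dataclass(frozen=True)
class StreetSegment:
    """A single street segment: an open polyline between two graph nodes."""

    id: Hashable
    polyline: Tuple[Point, ...]
    length: float
    end_nodes: Tuple[int, int]

    def __post_init__(self):
        if self.length <= 0:
            raise StreetGraphError(f"segment {self.id}: length must be > 0")
        expect = polyline_length(self.polyline)
        if not math.isclose(expect, self.length, rel_tol=1e-6):
            raise StreetGraphError(
                f"segment {self.id}: stored length {self.length} != polyline length {expect}"
            )

    def direction_away_from(self, node_coord: Point) -> Tuple[float, float]:
        """Unit vector from ``node_coord`` toward the adjacent polyline vertex."""
        p0 = np.asarray(self.polyline[0], dtype=float)
        p1 = np.asarray(self.polyline[-1], dtype=float)
        nc = np.asarray(node_coord, dtype=float)
        if np.hypot(*(p0 - nc)) <= np.hypot(*(p1 - nc)):
            a, b = np.asarray(self.polyline[0]), np.asarray(self.polyline[1])
        else:
            a, b = np.asarray(self.polyline[-1]), np.asarray(self.polyline[-2])
        v = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
        n = np.hypot(*v)
        if n == 0:
            raise StreetGraphError(f"segment {self.id}: degenerate direction at node")
        return (float(v[0] / n), float(v[1] / n))

    def geometry(self) -> LineString:
        return LineString(self.polyline)


@dataclass
class SegmentGraph:
    """Street segments plus node incidence and angular turn costs."""

    segments: Dict[Hashable, StreetSegment]
    node_coords: Dict[int, Point]
    node_incidence: Dict[int, Set[Hashable]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.node_incidence:
            inc: Dict[int, Set[Hashable]] = {n: set() for n in self.node_coords}
            for seg in self.segments.values():
                for n in seg.end_nodes:
                    inc[n].add(seg.id)
            self.node_incidence = inc

    # -- basic queries ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.segments)

    def segment_ids(self) -> List[Hashable]:
        return list(self.segments)

    def shared_nodes(self, a: Hashable, b: Hashable) -> List[int]:
        sa = set(self.segments[a].end_nodes)
        sb = set(self.segments[b].end_nodes)
        return sorted(sa & sb)

    def turn_cost(self, a: Hashable, b: Hashable, node: int) -> float:
        return angular_turn_cost(self.segments[a], self.segments[b], node, self)

    def node_graph(self) -> nx.Graph:
        """Undirected node graph weighted by segment length (cached)."""
        g = getattr(self, "_node_graph", None)
        if g is None:
            g = nx.Graph()
            g.add_nodes_from(self.node_coords)
            for seg in self.segments.values():
                u, v = seg.end_nodes
                if g.has_edge(u, v):
                    if seg.length < g[u][v]["weight"]:
                        g[u][v]["weight"] = seg.length
                        g[u][v]["segment"] = seg.id
                else:
                    g.add_edge(u, v, weight=seg.length, segment=seg.id)
            self._node_graph = g
        return g

    def connected(self) -> bool:
        g = self.node_graph()
        return g.number_of_nodes() > 0 and nx.is_connected(g)

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, segments_path, turns_path) -> None:
        """Write the graph as two CSVs: segments with WKT geometry, and the
        turn-cost edge list (segment pair, shared node, degrees)."""
        with open(segments_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["segment_id", "wkt", "length_m", "node_a", "node_b"])
            for seg in self.segments.values():
                w.writerow(
                    [seg.id, seg.geometry().wkt, repr(seg.length), *seg.end_nodes]
                )
        with open(turns_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["segment_a", "segment_b", "node", "turn_deg"])
            for node, inc in sorted(self.node_incidence.items()):
                inc_sorted = sorted(inc, key=str)
                for i, a in enumerate(inc_sorted):
                    for b in inc_sorted[i + 1 :]:
                        w.writerow([a, b, node, repr(self.turn_cost(a, b, node))])

    @classmethod
    def from_csv(cls, segments_path) -> "SegmentGraph":
        """Rebuild a graph from the segments CSV written by :meth:`to_csv`.

        Node ids are taken from the file, node coordinates recovered from the
        polyline endpoints; the turn-cost list is recomputable so it is not
        required for the round trip.
        """
        segments: Dict[Hashable, StreetSegment] = {}
        node_coords: Dict[int, Point] = {}
        with open(segments_path, newline="") as fh:
            for row in csv.DictReader(fh):
                geom = shapely_wkt.loads(row["wkt"])
                poly = tuple((float(x), float(y)) for x, y in geom.coords)
                na, nb = int(row["node_a"]), int(row["node_b"])
                sid: Hashable = row["segment_id"]
                try:
                    sid = int(sid)
                except (TypeError, ValueError):
                    pass
                segments[sid] = StreetSegment(
                    id=sid, polyline=poly, length=float(row["length_m"]), end_nodes=(na, nb)
                )
                node_coords[na] = poly[0]
                node_coords[nb] = poly[-1]
        return cls(segments=segments, node_coords=node_coords)


def angular_turn_cost(
    a: StreetSegment, b: StreetSegment, node: int, graph: "SegmentGraph"
) -> float:
    """Angular deviation, in degrees, of travelling from segment ``a`` into
    segment ``b`` through their shared ``node``.

    Straight continuation costs 0, a right angle 90, a full reversal 180.  The
    direction of each segment is taken from its polyline vertex adjacent to
    the node, so the cost is invariant to the stored vertex order.
    """
    for seg in (a, b):
        if node not in seg.end_nodes:
            raise StreetGraphError(f"segment {seg.id} not incident to node {node}")
    nc = graph.node_coords[node]
    da = a.direction_away_from(nc)
    db = b.direction_away_from(nc)
    # Arrival direction along a is -da; deviation = angle(-da, db).
    dot = -(da[0] * db[0] + da[1] * db[1])
    dot = min(1.0, max(-1.0, dot))
    return math.degrees(math.acos(dot))


# ---------------------------------------------------------------------------
# Construction


def _looks_geographic(coords: np.ndarray) -> bool:
    x, y = coords[:, 0], coords[:, 1]
    return bool(
        x.min() >= -180 and x.max() <= 180 and y.min() >= -90 and y.max() <= 90
    )


def _cluster_endpoints(points: np.ndarray, tol: float) -> np.ndarray:
    """Union-find clustering of endpoints within ``tol``; returns labels."""
    n = len(points)
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    if tol > 0 and n > 1:
        tree = cKDTree(points)
        for i, j in tree.query_pairs(tol):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri
    labels = np.fromiter((find(i) for i in range(n)), dtype=int, count=n)
    # relabel compactly, stable in first-appearance order
    _, inv = np.unique(labels, return_inverse=True)
    order = {}
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(inv):
        if lab not in order:
            order[lab] = len(order)
        out[i] = order[lab]
    return out


def build_segment_graph(
    centerlines: Iterable[Sequence[Point]],
    snap_tolerance: float = DEFAULT_SNAP_TOLERANCE,
    allow_loops: bool = False,
    allow_multi_edges: bool = False,
    merge_collinear: bool = False,
    collinear_tolerance_deg: float = 5.0,
) -> SegmentGraph:
    """Build a :class:`SegmentGraph` from raw centerline polylines.

    Endpoints within ``snap_tolerance`` are merged into a single node (the
    cluster centroid), zero-length segments are dropped, and exact duplicate
    geometries are deduplicated.  Loops (both endpoints on one node) and
    multi-edges (two distinct geometries joining the same node pair) are
    rejected unless the corresponding flag is set.

    With ``merge_collinear`` set, chains meeting at degree-2 nodes are fused
    into single segments while the accumulated angular deviation of the chain
    stays below ``collinear_tolerance_deg``.
    """
    lines = [tuple((float(x), float(y)) for x, y in pl) for pl in centerlines]
    lines = [pl for pl in lines if len(pl) >= 2]
    if not lines:
        raise StreetGraphError("no segments")
    if snap_tolerance < 0:
        raise StreetGraphError("snap_tolerance must be >= 0")

    allc = np.array([p for pl in lines for p in pl], dtype=float)
    if _looks_geographic(allc):
        raise StreetGraphError(
            "coordinates look geographic (degrees); project to a planar "
            "metric CRS before building the graph"
        )

    endpoints = np.array([p for pl in lines for p in (pl[0], pl[-1])], dtype=float)
    labels = _cluster_endpoints(endpoints, snap_tolerance)
    n_nodes = labels.max() + 1
    node_coords: Dict[int, Point] = {}
    for lab in range(n_nodes):
        pts = endpoints[labels == lab]
        node_coords[lab] = (float(pts[:, 0].mean()), float(pts[:, 1].mean()))

    segments: Dict[Hashable, StreetSegment] = {}
    seen_geoms: Set[Tuple[Point, ...]] = set()
    pair_geoms: Dict[Tuple[int, int], Tuple[Point, ...]] = {}
    sid = 0
    for k, pl in enumerate(lines):
        na, nb = int(labels[2 * k]), int(labels[2 * k + 1])
        poly = (node_coords[na],) + tuple(pl[1:-1]) + (node_coords[nb],)
        length = polyline_length(poly)
        if length <= snap_tolerance or length == 0.0:
            continue  # collapsed by snapping
        canon = min(poly, poly[::-1])
        if canon in seen_geoms:
            continue  # exact duplicate
        seen_geoms.add(canon)
        if na == nb and not allow_loops:
            raise StreetGraphError(f"loop segment at node {na} (centerline #{k}); "
                                   "pass allow_loops=True to keep it")
        key = (min(na, nb), max(na, nb))
        if key in pair_geoms and na != nb and not allow_multi_edges:
            raise StreetGraphError(
                f"multi-edge between nodes {key} (centerline #{k}); "
                "pass allow_multi_edges=True to keep it"
            )
        pair_geoms.setdefault(key, poly)
        segments[sid] = StreetSegment(id=sid, polyline=poly, length=length, end_nodes=(na, nb))
        sid += 1

    if not segments:
        raise StreetGraphError("no segments")
    g = SegmentGraph(segments=segments, node_coords=node_coords)
    if merge_collinear:
        g = _merge_collinear_chains(g, collinear_tolerance_deg)
    return g


def _merge_collinear_chains(g: SegmentGraph, tol_deg: float) -> SegmentGraph:
    """Fuse segments across degree-2 nodes while accumulated deviation < tol."""
    deviation: Dict[Hashable, float] = {s: 0.0 for s in g.segments}
    segments = dict(g.segments)
    incidence = {n: set(s) for n, s in g.node_incidence.items()}

    def rebuild(a: StreetSegment, b: StreetSegment, node: int) -> StreetSegment:
        pa = list(a.polyline)
        pb = list(b.polyline)
        nc = g.node_coords[node]
        if math.dist(pa[0], nc) < math.dist(pa[-1], nc):
            pa.reverse()
        if math.dist(pb[-1], nc) < math.dist(pb[0], nc):
            pb.reverse()
        poly = tuple(pa) + tuple(pb[1:])
        ends = tuple(n for s in (a, b) for n in s.end_nodes if n != node)
        return StreetSegment(
            id=a.id, polyline=poly, length=polyline_length(poly), end_nodes=(ends[0], ends[1])
        )

    changed = True
    while changed:
        changed = False
        for node in list(incidence):
            inc = incidence.get(node, set())
            if len(inc) != 2:
                continue
            a_id, b_id = sorted(inc, key=str)
            a, b = segments[a_id], segments[b_id]
            if a.id == b.id or node not in a.end_nodes or node not in b.end_nodes:
                continue
            cost = angular_turn_cost(a, b, node, g)
            total = deviation[a_id] + deviation[b_id] + cost
            if total >= tol_deg:
                continue
            merged = rebuild(a, b, node)
            if merged.end_nodes[0] == merged.end_nodes[1]:
                continue  # would create a loop
            segments[merged.id] = merged
            del segments[b_id]
            deviation[merged.id] = total
            del deviation[b_id]
            incidence.pop(node)
            for n in merged.end_nodes:
                incidence[n] = (incidence[n] - {a_id, b_id}) | {merged.id}
            changed = True
            break
    coords = {n: g.node_coords[n] for n in incidence}
    return SegmentGraph(segments=segments, node_coords=coords)


# ---------------------------------------------------------------------------
# Metric distances between segments

INF = math.inf


def network_distance(g: SegmentGraph, i: Hashable, j: Hashable) -> float:
    """Shortest along-network distance between the midpoints of segments
    ``i`` and ``j``, counting half of each segment's length.

    ``distance(i, i) == 0``; a disconnected pair yields ``math.inf``.
    """
    if i not in g.segments or j not in g.segments:
        raise StreetGraphError("segment id not in graph")
    if i == j:
        return 0.0
    return network_distances_from(g, i)[j]


def network_distances_from(g: SegmentGraph, i: Hashable) -> Dict[Hashable, float]:
    """Midpoint-to-midpoint network distances from segment ``i`` to all
    segments (inf where unreachable)."""
    seg_i = g.segments[i]
    ng = g.node_graph()
    half_i = seg_i.length / 2.0
    du = nx.single_source_dijkstra_path_length(ng, seg_i.end_nodes[0], weight="weight")
    dv = nx.single_source_dijkstra_path_length(ng, seg_i.end_nodes[1], weight="weight")
    out: Dict[Hashable, float] = {}
    for j, seg_j in g.segments.items():
        if j == i:
            out[j] = 0.0
            continue
        half_j = seg_j.length / 2.0
        best = INF
        for e in seg_j.end_nodes:
            cand = min(du.get(e, INF), dv.get(e, INF))
            if cand < best:
                best = cand
        out[j] = best + half_i + half_j if best < INF else INF
    return out


# ---------------------------------------------------------------------------
# GeoJSON centerline input


def read_centerlines_geojson(path) -> List[List[Point]]:
    """Read LineString / MultiLineString features from a GeoJSON file."""
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    lines: List[List[Point]] = []
    for feat in feats:
        geom = shape(feat["geometry"] if "geometry" in feat else feat)
        if geom.geom_type == "LineString":
            lines.append([(x, y) for x, y in geom.coords])
        elif geom.geom_type == "MultiLineString":
            for part in geom.geoms:
                lines.append([(x, y) for x, y in part.coords])
        else:
            raise StreetGraphError(f"unsupported geometry type {geom.geom_type}")
    if not lines:
        raise StreetGraphError("no segments")
    return lines
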