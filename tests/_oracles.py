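"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (exhaustive enumeration, O(n^2) scans)
and shares no code path with the implementation it checks.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, Hashable, List, Sequence, Set, Tuple

import numpy as np

TOL = 1e-9


# ---------------------------------------------------------------------------
# endpoint clustering (graph construction oracle)


def cluster_endpoints_brute(points: np.ndarray, tol: float) -> List[Set[int]]:
    """Transitive closure of the 'within tol' relation by repeated sweeps."""
    n = len(points)
    groups = [{i} for i in range(n)]
    merged = True
    while merged:
        merged = False
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                if any(
                    math.dist(points[i], points[j]) <= tol
                    for i in groups[a]
                    for j in groups[b]
                ):
                    groups[a] |= groups[b]
                    del groups[b]
                    merged = True
                    break
            if merged:
                break
    return groups


# ---------------------------------------------------------------------------
# independent adjacency / turn costs from first principles


def _direction_at(seg, node_coord) -> Tuple[float, float]:
    pts = list(seg.polyline)
    if math.dist(pts[0], node_coord) <= math.dist(pts[-1], node_coord):
        a, b = pts[0], pts[1]
    else:
        a, b = pts[-1], pts[-2]
    dx, dy = b[0] - a[0], b[1] - a[1]
    h = math.hypot(dx, dy)
    return dx / h, dy / h


def turn_cost_brute(g, a_id, b_id, node) -> float:
    a, b = g.segments[a_id], g.segments[b_id]
    nc = g.node_coords[node]
    da = _direction_at(a, nc)
    db = _direction_at(b, nc)
    dot = -(da[0] * db[0] + da[1] * db[1])
    return math.degrees(math.acos(max(-1.0, min(1.0, dot))))


def dual_adjacency_brute(g) -> Dict[Hashable, Dict[Hashable, float]]:
    adj: Dict[Hashable, Dict[Hashable, float]] = {s: {} for s in g.segments}
    for node, inc in g.node_incidence.items():
        for a, b in itertools.combinations(sorted(inc, key=str), 2):
            c = turn_cost_brute(g, a, b, node)
            if b not in adj[a] or c < adj[a][b]:
                adj[a][b] = c
                adj[b][a] = c
    return adj


# ---------------------------------------------------------------------------
# tied least-angular-cost paths (enumeration with admissible pruning)


def _relaxation_costs(adj, source) -> Dict[Hashable, float]:
    """Single-source least cumulative costs by repeated edge relaxation
    (Bellman-Ford style; independent of the implementation's heap Dijkstra)."""
    cost = {s: math.inf for s in adj}
    cost[source] = 0.0
    changed = True
    while changed:
        changed = False
        for s in adj:
            cs = cost[s]
            if cs == math.inf:
                continue
            for t, w in adj[s].items():
                if cs + w < cost[t] - 1e-15:
                    cost[t] = cs + w
                    changed = True
    return cost


def least_cost_brute(g, i, j, adj=None):
    """(min cumulative angular cost, list of tied least-cost simple paths).

    Exhaustive DFS over the dual adjacency, pruned with the admissible bound
    cost-so-far + least-cost-to-target <= min + slack, which enumerates
    exactly the tied minimal paths without visiting the (exponentially many)
    suboptimal ones.
    """
    if adj is None:
        adj = dual_adjacency_brute(g)
    dist_to_j = _relaxation_costs(adj, j)  # symmetric costs: to == from
    best = dist_to_j.get(i, math.inf)
    if best == math.inf:
        return math.inf, []
    slack = 1e-7
    tied: List[Tuple[List[Hashable], float]] = []

    def dfs(s, path, cost):
        if s == j:
            tied.append((list(path), cost))
            return
        for t, w in adj[s].items():
            nc = cost + w
            if t in path or nc + dist_to_j[t] > best + slack:
                continue
            path.append(t)
            dfs(t, path, nc)
            path.pop()

    dfs(i, [i], 0.0)
    true_min = min(c for _, c in tied)
    paths = [p for p, c in tied if c <= true_min + TOL]
    return true_min, paths


# ---------------------------------------------------------------------------
# metric segment distances (Floyd-Warshall, midpoint convention)


def metric_distances_brute(g) -> Dict[Tuple[Hashable, Hashable], float]:
    nodes = sorted(g.node_coords)
    idx = {n: k for k, n in enumerate(nodes)}
    n = len(nodes)
    d = np.full((n, n), math.inf)
    np.fill_diagonal(d, 0.0)
    for seg in g.segments.values():
        u, v = idx[seg.end_nodes[0]], idx[seg.end_nodes[1]]
        d[u, v] = min(d[u, v], seg.length)
        d[v, u] = d[u, v]
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    out = {}
    for i, si in g.segments.items():
        for j, sj in g.segments.items():
            if i == j:
                out[(i, j)] = 0.0
                continue
            best = min(
                d[idx[a], idx[b]]
                for a in si.end_nodes
                for b in sj.end_nodes
            )
            out[(i, j)] = best + si.length / 2 + sj.length / 2 if best < math.inf else math.inf
    return out


# ---------------------------------------------------------------------------
# movement potential (betweenness) oracle


def movement_potential_brute(g, radii: Sequence[float]) -> Dict[float, Dict[Hashable, float]]:
    """Exhaustive OD / tied-path enumeration with 1/t tie splitting."""
    sids = sorted(g.segments, key=str)
    metric = metric_distances_brute(g)
    adj = dual_adjacency_brute(g)
    acc = {r: {s: 0.0 for s in sids} for r in radii}
    for i, j in itertools.combinations(sids, 2):
        _, tied = least_cost_brute(g, i, j, adj=adj)
        if not tied:
            continue
        t = len(tied)
        for r in radii:
            if metric[(i, j)] > r:
                continue
            for path in tied:
                for mid in path[1:-1]:
                    acc[r][mid] += 1.0 / t
    return acc


# ---------------------------------------------------------------------------
# random test graphs


def random_graph_lines(rng: np.random.Generator, n_segments: int):
    """Random connected planar-ish centerline sets: a random spanning tree on
    random points plus a few extra short links, offset away from the
    geographic-coordinate guard."""
    n_nodes = max(3, n_segments - int(rng.integers(0, 3)))
    while n_nodes * (n_nodes - 1) // 2 < n_segments:
        n_nodes += 1  # enough node pairs to host the requested edges
    pts = rng.uniform(0.0, 600.0, size=(n_nodes, 2)) + np.array([1000.0, 200.0])
    edges = set()
    lines = []
    in_tree = [0]
    for k in range(1, n_nodes):
        a = int(rng.choice(in_tree))
        edges.add((min(a, k), max(a, k)))
        in_tree.append(k)
    while len(edges) < n_segments:
        a, b = rng.integers(0, n_nodes, size=2)
        if a == b:
            continue
        key = (min(int(a), int(b)), max(int(a), int(b)))
        if key in edges:
            continue
        edges.add(key)
    for a, b in sorted(edges):
        lines.append([tuple(pts[a]), tuple(pts[b])])
    return lines
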