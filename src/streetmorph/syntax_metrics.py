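"""Space-syntax accessibility metrics on a street-segment graph.

Two per-segment measures are computed:

* **connectivity** — the number of other segments sharing an endpoint node;
* **movement potential** (betweenness / "choice") — for every unordered pair
  of distinct segments whose midpoint-to-midpoint network distance is within a
  metric radius, all *angular* least-cost paths between them are found (path
  cost = cumulative angular deviation at the turns) and each intermediate
  segment on a path receives ``1/t`` where ``t`` is the number of tied paths.
  Origins and destinations receive nothing.  Both the raw tally and
  ``log10(1 + raw)`` are reported; the log variant is what enters the
  statistical models.

The radius restricts only the origin-destination set; path choice itself is
radius-independent, which makes the raw counts non-decreasing in the radius.
"""

from __future__ import annotations

import heapq
import math
from typing import Dict, Hashable, Iterable, List, Mapping, Sequence, Set, Tuple, Union

import pandas as pd

from .street_graph import SegmentGraph, StreetGraphError, network_distances_from

GLOBAL_RADIUS = math.inf

TIE_TOL = 1e-9  # absolute tolerance on cumulative angular cost

Radius = Union[float, str]


def _radius_value(radius: Radius) -> float:
    if isinstance(radius, str):
        if radius.lower() in ("global", "n", "rn"):
            return GLOBAL_RADIUS
        raise StreetGraphError(f"unknown radius {radius!r}")
    r = float(radius)
    if r <= 0:
        raise StreetGraphError("radius must be > 0")
    return r


def connectivity(g: SegmentGraph) -> Dict[Hashable, int]:
    """Number of distinct other segments sharing at least one endpoint."""
    out: Dict[Hashable, int] = {}
    for sid, seg in g.segments.items():
        neigh: Set[Hashable] = set()
        for n in seg.end_nodes:
            neigh |= g.node_incidence[n]
        neigh.discard(sid)
        out[sid] = len(neigh)
    return out


def segment_adjacency(g: SegmentGraph) -> Dict[Hashable, List[Tuple[Hashable, float]]]:
    """Dual-graph adjacency: for each segment, (neighbour, turn cost in deg).

    Where two segments share more than one node the cheapest turn is used.
    """
    adj: Dict[Hashable, Dict[Hashable, float]] = {s: {} for s in g.segments}
    for node, inc in g.node_incidence.items():
        inc_l = sorted(inc, key=str)
        for i, a in enumerate(inc_l):
            for b in inc_l[i + 1 :]:
                c = g.turn_cost(a, b, node)
                if b not in adj[a] or c < adj[a][b]:
                    adj[a][b] = c
                    adj[b][a] = c
    return {s: sorted(d.items(), key=lambda kv: str(kv[0])) for s, d in adj.items()}


def _dijkstra_costs(
    origin: Hashable,
    adjacency: Mapping[Hashable, Sequence[Tuple[Hashable, float]]],
    tol: float,
) -> Dict[Hashable, float]:
    """Least cumulative angular cost from ``origin`` to every reachable
    segment (plain Dijkstra on the dual graph)."""
    cost: Dict[Hashable, float] = {origin: 0.0}
    done: Set[Hashable] = set()
    heap: List[Tuple[float, int, Hashable]] = [(0.0, 0, origin)]
    counter = 1
    while heap:
        c, _, s = heapq.heappop(heap)
        if s in done:
            continue
        done.add(s)
        for t, turn in adjacency[s]:
            nc = cost[s] + turn
            if t not in cost or nc < cost[t] - tol:
                cost[t] = nc
                heapq.heappush(heap, (nc, counter, t))
                counter += 1
    return cost


def _tied_preds(
    origin: Hashable,
    cost: Mapping[Hashable, float],
    adjacency: Mapping[Hashable, Sequence[Tuple[Hashable, float]]],
    tol: float,
) -> Dict[Hashable, Set[Hashable]]:
    """All tied predecessors: p precedes t when cost[p] + turn(p,t) matches
    cost[t] within ``tol``.

    Built after the cost pass so that ties across zero-cost (collinear)
    continuations between equal-cost segments are captured in both
    directions; the origin keeps an empty set (its only least-cost path is
    the trivial one).
    """
    preds: Dict[Hashable, Set[Hashable]] = {s: set() for s in cost}
    for t in cost:
        if t == origin:
            continue
        ct = cost[t]
        for p, turn in adjacency[t]:
            if p in cost and abs(cost[p] + turn - ct) <= tol:
                preds[t].add(p)
    return preds


def _topological_order(
    cost: Mapping[Hashable, float], preds: Mapping[Hashable, Set[Hashable]]
) -> List[Hashable] | None:
    """Kahn topological order of the tied-predecessor relation, or ``None``
    when it has cycles (zero-cost plateaus of mutually tied segments)."""
    indeg = {s: len(preds[s]) for s in cost}
    succ: Dict[Hashable, List[Hashable]] = {s: [] for s in cost}
    for t, ps in preds.items():
        for p in ps:
            succ[p].append(t)
    ready = sorted((s for s, d in indeg.items() if d == 0),
                   key=lambda k: (cost[k], str(k)))
    heap = [(cost[s], str(s), s) for s in ready]
    heapq.heapify(heap)
    order: List[Hashable] = []
    while heap:
        _, _, s = heapq.heappop(heap)
        order.append(s)
        for t in succ[s]:
            indeg[t] -= 1
            if indeg[t] == 0:
                heapq.heappush(heap, (cost[t], str(t), t))
    if len(order) != len(cost):
        return None
    return order


_ENUM_STEP_CAP = 5_000_000


def _enumerate_tied_paths(
    origin: Hashable,
    cost: Mapping[Hashable, float],
    adjacency: Mapping[Hashable, Sequence[Tuple[Hashable, float]]],
    tol: float,
):
    """Exact fallback for graphs with zero-cost plateaus: depth-first
    enumeration of every simple path along tied edges from ``origin``.

    Every such path is a least-angular-cost path to its endpoint (the edge
    costs telescope to the endpoint's label), and conversely every least-cost
    path uses only tied edges.  Yields ``(target, path)`` tuples with the
    path given as a list of segments from origin to target.
    """
    tied_succ: Dict[Hashable, List[Hashable]] = {s: [] for s in cost}
    for t in cost:
        if t == origin:
            continue
        for p, turn in adjacency[t]:
            if p in cost and abs(cost[p] + turn - cost[t]) <= tol:
                tied_succ[p].append(t)
    path = [origin]
    on_path = {origin}
    steps = 0

    def dfs(s: Hashable):
        nonlocal steps
        for t in tied_succ[s]:
            if t in on_path:
                continue
            steps += 1
            if steps > _ENUM_STEP_CAP:
                raise StreetGraphError(
                    "tie structure too rich for exact enumeration; "
                    "perturb the geometry or reduce the graph"
                )
            path.append(t)
            on_path.add(t)
            yield t, list(path)
            yield from dfs(t)
            path.pop()
            on_path.discard(t)

    yield from dfs(origin)


def angular_least_cost_tree(
    g: SegmentGraph,
    origin: Hashable,
    adjacency: Mapping[Hashable, Sequence[Tuple[Hashable, float]]] | None = None,
    tol: float = TIE_TOL,
) -> Tuple[Dict[Hashable, float], Dict[Hashable, Set[Hashable]]]:
    """Single-source least-cumulative-angular-cost tree over segments.

    Returns ``(cost, predecessors)`` where ``cost[origin] == 0`` and
    ``predecessors[s]`` holds *all* predecessors on paths tied (within
    ``tol``) for the least cumulative cost.  Unreachable segments are absent
    from both maps.
    """
    if origin not in g.segments:
        raise StreetGraphError(f"origin segment {origin!r} not in graph")
    if adjacency is None:
        adjacency = segment_adjacency(g)
    cost = _dijkstra_costs(origin, adjacency, tol)
    preds = _tied_preds(origin, cost, adjacency, tol)
    return cost, preds


def _path_counts(
    order: Sequence[Hashable], preds: Mapping[Hashable, Set[Hashable]]
) -> Dict[Hashable, float]:
    """Number of tied least-cost paths from the origin to each segment."""
    sigma: Dict[Hashable, float] = {}
    for s in order:
        ps = preds[s]
        sigma[s] = 1.0 if not ps else sum(sigma[p] for p in ps)
    return sigma


def movement_potential(
    g: SegmentGraph,
    radius: Radius | Sequence[Radius] = GLOBAL_RADIUS,
) -> Union[Dict[Hashable, float], Dict[float, Dict[Hashable, float]]]:
    """Raw movement-potential (tie-split angular betweenness) per segment.

    ``radius`` may be a single metric radius (or ``"global"``/``math.inf``) or
    a sequence of radii, in which case a ``{radius: {segment: raw}}`` map is
    returned with all radii computed in one sweep.
    """
    single = not isinstance(radius, (list, tuple))
    radii = [_radius_value(radius)] if single else [_radius_value(r) for r in radius]

    adjacency = segment_adjacency(g)
    sids = list(g.segments)
    acc: Dict[float, Dict[Hashable, float]] = {r: {s: 0.0 for s in sids} for r in radii}

    for origin in sids:
        cost = _dijkstra_costs(origin, adjacency, TIE_TOL)
        preds = _tied_preds(origin, cost, adjacency, TIE_TOL)
        metric = None
        if any(r < GLOBAL_RADIUS for r in radii):
            metric = network_distances_from(g, origin)
        # targets eligible per radius
        eligible: Dict[float, Set[Hashable]] = {}
        for r in radii:
            if r == GLOBAL_RADIUS:
                eligible[r] = {s for s in cost if s != origin}
            else:
                eligible[r] = {
                    s for s in cost if s != origin and metric[s] <= r
                }
        order = _topological_order(cost, preds)
        if order is not None:
            # Brandes-style accumulation over the tied-paths DAG, one delta
            # per radius, in reverse topological order
            sigma = _path_counts(order, preds)
            delta: Dict[Hashable, List[float]] = {s: [0.0] * len(radii) for s in cost}
            for w in reversed(order):
                coef = [
                    (1.0 if w in eligible[r] else 0.0) + delta[w][k]
                    for k, r in enumerate(radii)
                ]
                for p in preds[w]:
                    frac = sigma[p] / sigma[w]
                    dp = delta[p]
                    for k in range(len(radii)):
                        dp[k] += frac * coef[k]
            for s in cost:
                if s == origin:
                    continue
                for k, r in enumerate(radii):
                    acc[r][s] += delta[s][k]
        else:
            # zero-cost plateau (mutually tied collinear segments): exact
            # enumeration of all tied simple paths from this origin
            by_target: Dict[Hashable, List[List[Hashable]]] = {}
            for target, path in _enumerate_tied_paths(origin, cost, adjacency, TIE_TOL):
                by_target.setdefault(target, []).append(path)
            for target, paths in by_target.items():
                t = len(paths)
                for k, r in enumerate(radii):
                    if target not in eligible[r]:
                        continue
                    for path in paths:
                        for mid in path[1:-1]:
                            acc[r][mid] += 1.0 / t

    # every unordered pair was visited from both ends
    for r in radii:
        for s in acc[r]:
            acc[r][s] /= 2.0
    if single:
        return acc[radii[0]]
    return acc


def movement_potential_log(raw: Mapping[Hashable, float]) -> Dict[Hashable, float]:
    """``log10(1 + raw)`` transform of a raw movement-potential map."""
    return {s: math.log10(1.0 + v) for s, v in raw.items()}


def syntax_table(
    g: SegmentGraph,
    radii: Sequence[Radius] = (1200.0, 3000.0, GLOBAL_RADIUS),
) -> pd.DataFrame:
    """Per-segment table of connectivity and movement potential at ``radii``.

    Columns: ``connectivity``, then ``mp_r{R}_raw`` / ``mp_r{R}_log`` per
    radius with ``R`` = integer metres or ``global``.
    """
    conn = connectivity(g)
    mp = movement_potential(g, list(radii))
    rows = {}
    rvals = [_radius_value(r) for r in radii]
    for sid in g.segments:
        row = {"connectivity": conn[sid]}
        for r in rvals:
            label = "global" if r == GLOBAL_RADIUS else str(int(r))
            row[f"mp_r{label}_raw"] = mp[r][sid]
            row[f"mp_r{label}_log"] = math.log10(1.0 + mp[r][sid])
        rows[sid] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "segment_id"
    return df


def write_syntax_geojson(g: SegmentGraph, table: pd.DataFrame, path) -> None:
    """Write segments with their syntax metrics as a GeoJSON layer."""
    import json

    feats = []
    for sid, seg in g.segments.items():
        props = {"segment_id": sid}
        props.update({k: float(v) for k, v in table.loc[sid].items()})
        feats.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [list(p) for p in seg.polyline],
                },
                "properties": props,
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
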