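"""Per-dwelling built- and natural-environment morphometrics.

All neighbourhood measures are evaluated inside catchments around a dwelling:

* a **street-network ("sausage") buffer** — the portion of the street network
  reachable within a network distance (default 1 km) of the dwelling's access
  point, buffered to a corridor of configurable half-width (default 50 m) —
  used for the land-use mix index, destination densities and the standard
  deviation of terrain slope;
* a **circular buffer** (default 500 m) used for mean greenness (NDVI);
* a **30 m disc** around the dwelling for dwelling-centred density.

The land-use mix index is the normalised entropy of land-area shares over the
five-category classification (residential, retail, community services,
business & offices, recreation & leisure):

    LUM = -sum_k p_k ln(p_k) / ln(N),   N = 5,

which is 0 for a single-use catchment and 1 when all five categories hold
equal area; zero shares contribute zero by the usual limit convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Hashable, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point as ShPoint, Polygon
from shapely.ops import substring, unary_union
from shapely.strtree import STRtree

from .street_graph import SegmentGraph, StreetGraphError

import networkx as nx

XY = Tuple[float, float]

LAND_USE_CLASSES = (
    "residential",
    "retail",
    "community_services",
    "business_offices",
    "recreation_leisure",
)

DESTINATION_CATEGORIES = (
    "bus_stops",
    "retail",
    "community_services",
    "recreation_leisure",
    "business_offices",
)

DEFAULT_HALF_WIDTH = 50.0     # metres; sausage-buffer corridor half-width
DEFAULT_SNAP_DISTANCE = 200.0  # metres; max dwelling-to-network gap
DWELLING_KERNEL_RADIUS = 30.0  # metres
PLOT_EXPOSURE_TOL = 2.0        # metres

# Canonical output column names (descriptive-table variable labels).
COL_DWELLING_DENSITY = "Dwelling centred density (within 30 m radius)"
COL_DWELLING_TYPE = "Dwelling type"
COL_PLOT_EXPOSURE = "Plot exposure"
COL_LUM = "Land use mix"
COL_DENSITY = {
    "bus_stops": "Density of bus stops",
    "retail": "Density of retail",
    "community_services": "Density of community services",
    "recreation_leisure": "Density of recreation & leisure facilities",
    "business_offices": "Density of business & offices",
}
COL_MP1200 = "Street movement potential R1200 m"
COL_MP3000 = "Street movement potential R3000 m"
COL_MPGLOBAL = "Street movement potential RN m"
COL_CONNECTIVITY = "Connectivity"
COL_SLOPE_SD = "Neighbourhood slope variability"
COL_NDVI = "Mean NDVI"

BUILT_ENV_COLUMNS = (
    COL_DWELLING_DENSITY,
    COL_DWELLING_TYPE,
    COL_PLOT_EXPOSURE,
    COL_LUM,
    *COL_DENSITY.values(),
    COL_MP1200,
    COL_MP3000,
    COL_MPGLOBAL,
    COL_CONNECTIVITY,
)
NATURAL_ENV_COLUMNS = (COL_SLOPE_SD, COL_NDVI)


class MorphometricsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Rasters


@dataclass
class RasterGrid:
    """A regular planar raster: values[0, 0] is the north-west cell."""

    x_ll: float
    y_ll: float
    cell_size: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.cell_size <= 0:
            raise MorphometricsError("cell size must be > 0")
        if self.values.ndim != 2:
            raise MorphometricsError("raster values must be 2-D")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    def cell_centers(self) -> Tuple[np.ndarray, np.ndarray]:
        """Meshgrid arrays (xs, ys) of cell-centre coordinates."""
        nrows, ncols = self.values.shape
        xs = self.x_ll + (np.arange(ncols) + 0.5) * self.cell_size
        ys = self.y_ll + (nrows - np.arange(nrows) - 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    # ESRI ASCII grid (plain text) I/O
    def to_ascii(self, path) -> None:
        nrows, ncols = self.values.shape
        vals = np.where(np.isnan(self.values), self.nodata, self.values)
        with open(path, "w") as fh:
            fh.write(f"ncols {ncols}\n")
            fh.write(f"nrows {nrows}\n")
            fh.write(f"xllcorner {self.x_ll!r}\n")
            fh.write(f"yllcorner {self.y_ll!r}\n")
            fh.write(f"cellsize {self.cell_size!r}\n")
            fh.write(f"NODATA_value {self.nodata!r}\n")
            np.savetxt(fh, vals, fmt="%.10g")

    @classmethod
    def from_ascii(cls, path) -> "RasterGrid":
        header: Dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            vals = np.loadtxt(fh)
        vals = np.atleast_2d(vals)
        return cls(
            x_ll=header["xllcorner"],
            y_ll=header["yllcorner"],
            cell_size=header["cellsize"],
            values=vals,
            nodata=header.get("nodata_value", -9999.0),
        )


def zonal_stat(raster: RasterGrid, zone, stat: str) -> float:
    """Mean or population standard deviation of raster cells whose centres
    fall inside ``zone``; nodata cells are ignored.

    Raises if the zone covers no valid cell centre.
    """
    if stat not in ("mean", "sd"):
        raise MorphometricsError(f"unknown statistic {stat!r}")
    # restrict to the raster window covering the zone's bounding box
    nrows, ncols = raster.values.shape
    x0, y0, x1, y1 = zone.bounds
    c0 = max(0, int((x0 - raster.x_ll) / raster.cell_size) - 1)
    c1 = min(ncols, int((x1 - raster.x_ll) / raster.cell_size) + 2)
    r0 = max(0, int((raster.y_ll + nrows * raster.cell_size - y1) / raster.cell_size) - 1)
    r1 = min(nrows, int((raster.y_ll + nrows * raster.cell_size - y0) / raster.cell_size) + 2)
    if c0 >= c1 or r0 >= r1:
        raise MorphometricsError("zone overlaps no valid raster cells")
    xs = raster.x_ll + (np.arange(c0, c1) + 0.5) * raster.cell_size
    ys = raster.y_ll + (nrows - np.arange(r0, r1) - 0.5) * raster.cell_size
    xs, ys = np.meshgrid(xs, ys)
    shapely.prepare(zone)
    inside = shapely.contains_xy(zone, xs.ravel(), ys.ravel()).reshape(xs.shape)
    vals = raster.values[r0:r1, c0:c1]
    valid = inside & (vals != raster.nodata) & ~np.isnan(vals)
    picked = vals[valid]
    if picked.size == 0:
        raise MorphometricsError("zone overlaps no valid raster cells")
    if stat == "mean":
        return float(picked.mean())
    return float(picked.std(ddof=0))


# ---------------------------------------------------------------------------
# Parcels, destinations, dwellings


@dataclass
class ParcelLayer:
    """Classified land-use polygons drawn from the closed 5-category set."""

    polygons: List[Polygon]
    classes: List[str]

    def __post_init__(self):
        if len(self.polygons) != len(self.classes):
            raise MorphometricsError("polygons and classes length mismatch")
        bad = set(self.classes) - set(LAND_USE_CLASSES)
        if bad:
            raise MorphometricsError(f"unknown land-use classes: {sorted(bad)}")

    def tree(self) -> STRtree:
        t = getattr(self, "_tree", None)
        if t is None:
            t = STRtree(self.polygons)
            self._tree = t
        return t


@dataclass
class DwellingRecord:
    id: Hashable
    point: XY
    dwelling_type: str = "detached"
    plot_exposure: str = "1"
    footprint: Optional[Polygon] = None

    DWELLING_TYPES = ("detached", "semi_detached", "terraced", "flat")
    EXPOSURE_LEVELS = ("0", "1", "2+")

    def __post_init__(self):
        if self.dwelling_type not in self.DWELLING_TYPES:
            raise MorphometricsError(f"unknown dwelling type {self.dwelling_type!r}")
        if self.plot_exposure not in self.EXPOSURE_LEVELS:
            raise MorphometricsError(f"unknown plot exposure {self.plot_exposure!r}")


# ---------------------------------------------------------------------------
# Network buffer


class SegmentLocator:
    """Nearest-segment lookup for a graph (STRtree over segment geometries)."""

    def __init__(self, g: SegmentGraph):
        self.g = g
        self.sids = list(g.segments)
        self.geoms = [g.segments[s].geometry() for s in self.sids]
        self.tree = STRtree(self.geoms)

    def locate(self, point: XY) -> Tuple[Hashable, float, float]:
        """Return (segment id, arclength of nearest point, gap distance)."""
        p = ShPoint(point)
        idx = int(self.tree.nearest(p))
        geom = self.geoms[idx]
        return self.sids[idx], float(geom.project(p)), float(geom.distance(p))


def _merge_intervals(iv: List[Tuple[float, float]]) -> List[Tuple[float, float]]:
    iv = sorted((lo, hi) for lo, hi in iv if hi > lo)
    out: List[Tuple[float, float]] = []
    for lo, hi in iv:
        if out and lo <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out


@dataclass
class NetworkBuffer:
    """Street-network catchment around a dwelling: the reached portions of
    every segment (arclength sub-intervals) and their sausage polygon."""

    origin: XY
    radius: float
    access_point: XY
    access_segment: Hashable
    reached_edges: Dict[Hashable, List[Tuple[float, float]]]
    polygon: shapely.Geometry
    area: float

    def reached_length(self) -> float:
        return sum(hi - lo for iv in self.reached_edges.values() for lo, hi in iv)


def network_buffer(
    g: SegmentGraph,
    origin: XY,
    radius: float,
    half_width: float = DEFAULT_HALF_WIDTH,
    snap_distance: float = DEFAULT_SNAP_DISTANCE,
    dwelling_id: Hashable = None,
    locator: Optional[SegmentLocator] = None,
) -> NetworkBuffer:
    """Compute the network ("sausage") buffer of ``radius`` metres around the
    point ``origin``.

    The origin is projected onto its nearest segment (it must lie within
    ``snap_distance`` of the network); the reached sub-network comprises every
    centerline point within network distance ``radius`` of that access point,
    with partial segment coverage included.  The polygon is the union of the
    reached portions buffered by ``half_width`` (round caps), guaranteed to
    contain the access point.
    """
    if radius <= 0:
        raise MorphometricsError("radius must be > 0")
    if locator is None:
        locator = SegmentLocator(g)
    sid, t, gap = locator.locate(origin)
    if gap > snap_distance:
        raise MorphometricsError(
            f"dwelling {dwelling_id!r}: origin is {gap:.1f} m from the street "
            f"network (> snap distance {snap_distance} m)"
        )
    seg = g.segments[sid]
    u, v = seg.end_nodes
    L = seg.length
    ng = g.node_graph()
    du = nx.single_source_dijkstra_path_length(ng, u, weight="weight")
    dv = nx.single_source_dijkstra_path_length(ng, v, weight="weight")
    INF = math.inf
    # distance from access point to each node
    nd: Dict[int, float] = {}
    for n in ng.nodes:
        nd_n = min(t + du.get(n, INF), (L - t) + dv.get(n, INF))
        if nd_n <= radius:
            nd[n] = nd_n

    reached: Dict[Hashable, List[Tuple[float, float]]] = {}
    for osid, oseg in g.segments.items():
        a, b = oseg.end_nodes
        Lo = oseg.length
        iv: List[Tuple[float, float]] = []
        if osid == sid:
            iv.append((max(0.0, t - radius), min(Lo, t + radius)))
        if a in nd:
            hi = min(Lo, radius - nd[a])
            if hi > 0:
                iv.append((0.0, hi))
        if b in nd:
            lo = max(0.0, Lo - (radius - nd[b]))
            if lo < Lo:
                iv.append((lo, Lo))
        iv = _merge_intervals(iv)
        if iv:
            reached[osid] = iv

    access_geom = locator.geoms[locator.sids.index(sid)]
    access_point = access_geom.interpolate(t)
    pieces = [access_point.buffer(half_width)]
    for osid, ivs in reached.items():
        line = g.segments[osid].geometry()
        for lo, hi in ivs:
            if hi - lo <= 0:
                continue
            piece = substring(line, lo, hi)
            pieces.append(piece.buffer(half_width))
    poly = unary_union(pieces)
    return NetworkBuffer(
        origin=tuple(origin),
        radius=radius,
        access_point=(access_point.x, access_point.y),
        access_segment=sid,
        reached_edges=reached,
        polygon=poly,
        area=float(poly.area),
    )


# ---------------------------------------------------------------------------
# Catchment measures


def lum_from_shares(shares: Sequence[float], n_categories: int = len(LAND_USE_CLASSES)) -> float:
    """Normalised entropy of land-area shares: -sum p ln p / ln N."""
    p = np.asarray(shares, dtype=float)
    if p.sum() <= 0:
        raise MorphometricsError("no classified land")
    p = p / p.sum()
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / math.log(n_categories))


def land_use_mix(buffer: NetworkBuffer, parcels: ParcelLayer) -> float:
    """Entropy land-use-mix index of the parcel areas intersected with the
    buffer polygon, over the fixed 5-category classification.

    Returns a unitless value in [0, 1]; raises if no classified land falls
    inside the buffer.
    """
    areas = {k: 0.0 for k in LAND_USE_CLASSES}
    tree = parcels.tree()
    for idx in tree.query(buffer.polygon):
        poly = parcels.polygons[int(idx)]
        a = buffer.polygon.intersection(poly).area
        if a > 0:
            areas[parcels.classes[int(idx)]] += a
    total = sum(areas.values())
    if total <= 0:
        raise MorphometricsError("no classified land")
    return lum_from_shares([areas[k] for k in LAND_USE_CLASSES])


def destination_density(
    buffer: NetworkBuffer, points: Mapping[str, Sequence[XY]] | Sequence[XY]
) -> Dict[str, float] | float:
    """Destinations inside the buffer polygon per km² of buffer area.

    ``points`` may be a single coordinate sequence (returns one density) or a
    mapping category -> coordinates (returns a per-category map).
    """
    area_km2 = buffer.area / 1e6
    if area_km2 <= 0:
        raise MorphometricsError("buffer area must be > 0")

    def _count(pts: Sequence[XY]) -> float:
        if len(pts) == 0:
            return 0.0
        arr = np.asarray(pts, dtype=float)
        inside = shapely.contains_xy(buffer.polygon, arr[:, 0], arr[:, 1])
        return float(inside.sum())

    if isinstance(points, Mapping):
        return {cat: _count(pts) / area_km2 for cat, pts in points.items()}
    return _count(points) / area_km2


def dwelling_centred_density(
    all_dwellings: Sequence[XY] | np.ndarray,
    focal: XY,
    radius: float = DWELLING_KERNEL_RADIUS,
) -> int:
    """Count of dwelling points within ``radius`` (Euclidean) of the focal
    point, the focal dwelling itself included (minimum 1 when it is present
    in ``all_dwellings``)."""
    arr = np.asarray(all_dwellings, dtype=float)
    if arr.size == 0:
        return 0
    d2 = (arr[:, 0] - focal[0]) ** 2 + (arr[:, 1] - focal[1]) ** 2
    return int((d2 <= radius * radius).sum())


def plot_exposure(
    footprint: Polygon,
    public_space: Iterable[Polygon] | shapely.Geometry,
    tol: float = PLOT_EXPOSURE_TOL,
) -> str:
    """Categorise how many faces of a dwelling footprint front onto public
    space: a face is exposed when its midpoint lies within ``tol`` metres of
    the public-space geometry.  Returns "0", "1" or "2+".
    """
    if footprint.is_empty or footprint.area <= 0:
        raise MorphometricsError("degenerate footprint (zero area)")
    if not isinstance(public_space, shapely.Geometry):
        public_space = unary_union(list(public_space))
    coords = list(footprint.exterior.coords)
    n_exposed = 0
    for (x0, y0), (x1, y1) in zip(coords[:-1], coords[1:]):
        mid = ShPoint((x0 + x1) / 2.0, (y0 + y1) / 2.0)
        if public_space.distance(mid) <= tol:
            n_exposed += 1
    return "0" if n_exposed == 0 else ("1" if n_exposed == 1 else "2+")


def circular_buffer(point: XY, radius: float):
    """Euclidean ("airline") circular buffer used for the greenness measure."""
    if radius <= 0:
        raise MorphometricsError("radius must be > 0")
    return ShPoint(point).buffer(radius)


# ---------------------------------------------------------------------------
# Full per-dwelling battery


def _metric_radius_columns(syntax: pd.DataFrame) -> Tuple[str, str]:
    """The two finite-radius log movement-potential columns of a syntax table,
    ordered local then city scale (the canonical analysis uses 1200 m and
    3000 m, but scaled-down radii are accepted for small study areas)."""
    metric = sorted(
        (int(c[len("mp_r"):-len("_log")]), c)
        for c in syntax.columns
        if c.startswith("mp_r") and c.endswith("_log") and c != "mp_rglobal_log"
    )
    if len(metric) != 2:
        raise MorphometricsError(
            "syntax table must carry exactly two finite-radius log columns "
            f"plus the global one; found {[c for _, c in metric]}"
        )
    return metric[0][1], metric[1][1]


def dwelling_morphometrics(
    g: SegmentGraph,
    dwellings: Sequence[DwellingRecord],
    parcels: ParcelLayer,
    destinations: Mapping[str, Sequence[XY]],
    slope_raster: RasterGrid,
    ndvi_raster: RasterGrid,
    all_dwelling_points: Sequence[XY],
    syntax: pd.DataFrame,
    public_space=None,
    buffer_radius: float = 1000.0,
    half_width: float = DEFAULT_HALF_WIDTH,
    ndvi_radius: float = 500.0,
    kernel_radius: float = DWELLING_KERNEL_RADIUS,
    snap_distance: float = DEFAULT_SNAP_DISTANCE,
) -> pd.DataFrame:
    """Compute the full morphometric battery, one row per dwelling.

    ``syntax`` is the per-segment table from
    :func:`streetmorph.syntax_metrics.syntax_table`; each dwelling inherits
    the log-scale movement-potential and connectivity values of its nearest
    street segment.  Plot exposure is recomputed from footprints when both a
    footprint and ``public_space`` are given, otherwise the record's stored
    category is carried through.
    """
    locator = SegmentLocator(g)
    pts = np.asarray(all_dwelling_points, dtype=float)
    local_col, city_col = _metric_radius_columns(syntax)
    rows = []
    for dw in dwellings:
        buf = network_buffer(
            g, dw.point, buffer_radius, half_width=half_width,
            snap_distance=snap_distance, dwelling_id=dw.id, locator=locator,
        )
        dens = destination_density(buf, {c: destinations.get(c, []) for c in DESTINATION_CATEGORIES})
        if dw.footprint is not None and public_space is not None:
            exposure = plot_exposure(dw.footprint, public_space)
        else:
            exposure = dw.plot_exposure
        srow = syntax.loc[buf.access_segment]
        row = {
            "dwelling_id": dw.id,
            COL_DWELLING_DENSITY: dwelling_centred_density(pts, dw.point, kernel_radius),
            COL_DWELLING_TYPE: dw.dwelling_type,
            COL_PLOT_EXPOSURE: exposure,
            COL_LUM: land_use_mix(buf, parcels),
            **{COL_DENSITY[c]: dens[c] for c in DESTINATION_CATEGORIES},
            COL_MP1200: float(srow[local_col]),
            COL_MP3000: float(srow[city_col]),
            COL_MPGLOBAL: float(srow["mp_rglobal_log"]),
            COL_CONNECTIVITY: float(srow["connectivity"]),
            COL_SLOPE_SD: zonal_stat(slope_raster, buf.polygon, "sd"),
            COL_NDVI: zonal_stat(ndvi_raster, circular_buffer(dw.point, ndvi_radius), "mean"),
        }
        rows.append(row)
    return pd.DataFrame(rows).set_index("dwelling_id")
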