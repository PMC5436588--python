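"""Road-network indicators per grid cell, class, and period.

Roads come as classed polylines (two-class scheme: ``main`` = expressways /
highways / simply-built highways, ``secondary`` = cart and rural roads).
Four indicators summarise network density and configuration per cell:

SRL
    Sum of road length inside the cell per unit cell area (km km^-2).
DNR
    Euclidean distance from the cell centroid to the nearest road of the
    class anywhere in the network (km) — not restricted to the cell.
NON
    Number of planar-graph nodes inside the cell per unit area (km^-2).
MND
    Mean degree of those nodes; by convention reported per unit cell area
    (km^-2) to match the published unit, with the plain mean available via
    ``mnd_per_area=False``.

Node definition: the polylines are planarized (all crossings become shared
vertices), then degree-2 pass-through vertices are dissolved; what remains
are junctions (degree >= 3) and terminals (degree 1).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from shapely import STRtree, union_all
from shapely.ops import linemerge
from shapely.geometry import LineString, MultiLineString, Point
from shapely.geometry.base import BaseGeometry

from .geojson_io import read_features, write_features
from .gridding import GridCell, GridSystem

__all__ = [
    "RoadNetwork",
    "planarize",
    "srl",
    "dnr",
    "non_mnd",
    "metrics_table",
    "ROAD_CLASSES",
]

ROAD_CLASSES = ("main", "secondary")

#: coordinate quantum (m) for merging floating-point twin vertices
_SNAP = 1e-6


def _snap(x: float, y: float) -> tuple[float, float]:
    return (round(x / _SNAP) * _SNAP, round(y / _SNAP) * _SNAP)


def planarize(segments: Sequence[LineString], *, dedupe: bool = True) -> nx.MultiGraph:
    """Planarize polylines into a junction/terminal graph.

    All pairwise crossings become shared vertices, chains of degree-2
    vertices are dissolved into single edges, and exact duplicate
    geometries (digitization artifacts) are dropped first.  Zero-length
    segments are dropped with a warning.

    Returns a :class:`networkx.MultiGraph` whose nodes are snapped (x, y)
    tuples with a ``pos`` attribute and whose edges carry ``geometry`` and
    ``length`` (m).  Node degree is the number of incident road edges.
    """
    lines = [ln for ln in segments if isinstance(ln, LineString)]
    n_zero = sum(1 for ln in lines if ln.length == 0)
    if n_zero:
        warnings.warn(f"dropped {n_zero} zero-length segment(s)", stacklevel=2)
    lines = [ln for ln in lines if ln.length > 0]
    if dedupe:
        seen: dict[bytes, LineString] = {}
        for ln in lines:
            seen.setdefault(ln.wkb, ln)
        lines = list(seen.values())
    graph = nx.MultiGraph()
    if not lines:
        return graph
    # union nodes the arrangement (splits at crossings); linemerge dissolves
    # degree-2 pass-through vertices back into single chains
    noded = union_all(lines)
    merged = linemerge(noded) if not isinstance(noded, LineString) else noded
    if isinstance(merged, LineString):
        parts: Iterable[LineString] = [merged]
    else:
        parts = list(merged.geoms)
    for part in parts:
        a = _snap(*part.coords[0])
        b = _snap(*part.coords[-1])
        graph.add_node(a, pos=a)
        graph.add_node(b, pos=b)
        graph.add_edge(a, b, geometry=part, length=part.length)
    return graph


def srl(cell: GridCell, segments: Sequence[LineString] | MultiLineString) -> float:
    """Sum of road length clipped to the cell, per cell area (km km^-2)."""
    geoms = list(segments.geoms) if isinstance(segments, MultiLineString) else list(segments)
    if not geoms:
        return 0.0
    tree = STRtree(geoms)
    total_m = sum(
        geoms[i].intersection(cell.geometry).length for i in tree.query(cell.geometry)
    )
    area_km2 = cell.geometry.area / 1e6
    return (total_m / 1e3) / area_km2


def dnr(cell: GridCell | Point, segments: Sequence[LineString] | MultiLineString) -> float:
    """Distance (km) from the cell centroid to the nearest road of the class.

    Network-wide: the nearest segment may lie outside the cell.  Returns
    NaN when the class has no segments at all (the missing flag propagated
    to the cell table; models impute it downstream).
    """
    geoms = list(segments.geoms) if isinstance(segments, MultiLineString) else list(segments)
    if not geoms:
        return float("nan")
    point = cell.centroid if isinstance(cell, GridCell) else cell
    tree = STRtree(geoms)
    nearest = tree.nearest(point)
    return point.distance(geoms[nearest]) / 1e3


def non_mnd(
    cell: GridCell, graph: nx.MultiGraph, *, mnd_per_area: bool = True
) -> tuple[float, float]:
    """Node density and mean node degree for the cell.

    NON is the count of planarized-graph nodes inside the cell (half-open
    boundary rule) divided by the cell area in km^2.  MND is the mean
    degree of those nodes, divided by cell area when ``mnd_per_area`` (the
    published convention).  A cell with no nodes yields (0, 0).
    """
    area_km2 = cell.geometry.area / 1e6
    degrees = [
        d for node, d in graph.degree() if cell.contains_point(node[0], node[1])
    ]
    if not degrees:
        return 0.0, 0.0
    non_val = len(degrees) / area_km2
    mnd_val = float(np.mean(degrees))
    if mnd_per_area:
        mnd_val /= area_km2
    return non_val, mnd_val


@dataclass
class RoadNetwork:
    """Classed road polylines for one period, plus their planar graph."""

    period: str
    segments: list[LineString]
    classes: list[str]
    _graphs: dict[str | None, nx.MultiGraph] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if len(self.segments) != len(self.classes):
            raise ValueError("segments and classes must be parallel lists")
        bad = set(self.classes) - set(ROAD_CLASSES)
        if bad:
            raise ValueError(f"unknown road class(es) {sorted(bad)}; expected {ROAD_CLASSES}")

    def for_class(self, road_class: str | None) -> list[LineString]:
        if road_class is None:
            return list(self.segments)
        return [s for s, c in zip(self.segments, self.classes) if c == road_class]

    def graph(self, road_class: str | None = None) -> nx.MultiGraph:
        """Planarized graph for one class (or the whole network); cached."""
        if road_class not in self._graphs:
            self._graphs[road_class] = planarize(self.for_class(road_class))
        return self._graphs[road_class]

    def total_length(self, road_class: str | None = None) -> float:
        """Total polyline length in metres (before planarization dedupe)."""
        return sum(s.length for s in self.for_class(road_class))

    def to_geojson(self, path: str | Path) -> None:
        write_features(
            path,
            [
                (seg, {"class": cls, "period": self.period})
                for seg, cls in zip(self.segments, self.classes)
            ],
        )

    @classmethod
    def from_geojson(cls, path: str | Path, period: str | None = None) -> "RoadNetwork":
        feats = read_features(path)
        segs: list[LineString] = []
        classes: list[str] = []
        periods = set()
        for geom, props in feats:
            if period is not None and props.get("period") not in (None, period):
                continue
            segs.append(geom)
            classes.append(props.get("class", "main"))
            if "period" in props:
                periods.add(props["period"])
        label = period if period is not None else (periods.pop() if len(periods) == 1 else "all")
        return cls(period=label, segments=segs, classes=classes)


def metrics_table(
    grid: GridSystem,
    networks: Mapping[str, RoadNetwork],
    *,
    classes: Sequence[str] = ROAD_CLASSES,
    mnd_per_area: bool = True,
) -> pd.DataFrame:
    """All four indicators per (cell, period, class), wide format.

    Returns a DataFrame indexed by (cell_id, period) with columns
    ``{SRL,DNR,NON,MND}_{class}``.  DNR is NaN for a class with no
    segments anywhere in that period.
    """
    import shapely

    n_cells = len(grid.cells)
    cell_arr = np.array([c.geometry for c in grid.cells], dtype=object)
    centroids = np.array([c.centroid for c in grid.cells], dtype=object)
    areas_km2 = np.array([c.geometry.area for c in grid.cells]) / 1e6
    id_of_rowcol = grid.rowcol_to_id()
    pos_of_id = {cid: i for i, cid in enumerate(grid.cell_ids)}

    rows = []
    # identical segment sets recur across periods (a frozen road class);
    # compute each distinct geometry set once
    cache: dict[bytes, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
    for period, net in networks.items():
        for road_class in classes:
            segs = net.for_class(road_class)
            key = hashlib.md5(b"".join(sorted(s.wkb for s in segs))).digest()
            if key in cache:
                length_m, dnr_km, n_nodes, deg_sum = cache[key]
            else:
                graph = net.graph(road_class)
                length_m = np.zeros(n_cells)
                if segs:
                    seg_arr = np.array(segs, dtype=object)
                    tree = STRtree(segs)
                    ci, si = tree.query(cell_arr)
                    if len(ci):
                        clipped = shapely.length(
                            shapely.intersection(seg_arr[si], cell_arr[ci])
                        )
                        np.add.at(length_m, ci, clipped)
                    near = tree.query_nearest(centroids, all_matches=False)
                    dnr_km = np.full(n_cells, np.nan)
                    dnr_km[near[0]] = shapely.distance(
                        centroids[near[0]], seg_arr[near[1]]
                    ) / 1e3
                else:
                    dnr_km = np.full(n_cells, np.nan)
                # vectorized node-to-cell assignment (half-open rule)
                n_nodes = np.zeros(n_cells)
                deg_sum = np.zeros(n_cells)
                for node, degree in graph.degree():
                    cid = id_of_rowcol.get(grid.cell_index_of(node[0], node[1]))
                    if cid is not None:
                        i = pos_of_id[cid]
                        n_nodes[i] += 1
                        deg_sum[i] += degree
                cache[key] = (length_m, dnr_km, n_nodes, deg_sum)
            with np.errstate(invalid="ignore"):
                mnd = np.where(n_nodes > 0, deg_sum / np.maximum(n_nodes, 1), 0.0)
            if mnd_per_area:
                mnd = mnd / areas_km2
            for i, cell in enumerate(grid.cells):
                rows.append(
                    {
                        "cell_id": cell.id,
                        "period": period,
                        "class": road_class,
                        "SRL": (length_m[i] / 1e3) / areas_km2[i],
                        "DNR": dnr_km[i],
                        "NON": n_nodes[i] / areas_km2[i],
                        "MND": mnd[i],
                    }
                )
    long = pd.DataFrame(rows)
    wide = long.pivot_table(
        index=["cell_id", "period"], columns="class",
        values=["SRL", "DNR", "NON", "MND"], dropna=False,
    )
    wide.columns = [f"{metric}_{cls}" for metric, cls in wide.columns]
    return wide.sort_index()
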