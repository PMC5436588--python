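"""Regular grid-cell system, land filtering, and per-cell aggregation.

The analysis frame is a lattice of square cells (default 5 x 5 km) laid over
a land mask.  Cells keeping at least half their area on land are retained;
the rest are dropped to avoid biasing forest-cover proportions low in
coastal slivers.  Per-cell quantities are derived either by exact polygon
overlay (forest cover) or by averaging raster pixels whose centroids fall
inside the cell (elevation, slope, climatic potential productivity).

Conventions
-----------
* One projected planar CRS in metres for everything.
* Grid origin = the land-mask bounding-box lower-left corner snapped *down*
  to a multiple of the cell size, recorded on the :class:`GridSystem` for
  reproducibility.
* Points or pixel centroids exactly on a shared cell edge belong to the
  cell via the half-open rule ``[x0, x1) x [y0, y1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely import STRtree, box, make_valid, union_all
from shapely.geometry import Point, Polygon
from shapely.geometry.base import BaseGeometry

from .geojson_io import read_features, write_features
from .raster import Raster

__all__ = [
    "GridCell",
    "GridSystem",
    "build_grid",
    "overlay_nfc",
    "aggregate_raster",
    "polygonize_mask",
    "EmptyGridError",
]

#: minimum on-land fraction for a cell to enter the analysis
LAND_FRACTION_THRESHOLD = 0.5


class EmptyGridError(ValueError):
    """Raised when the grid extent does not intersect the land mask."""


@dataclass(frozen=True)
class GridCell:
    """One square analysis cell."""

    id: int
    row: int
    col: int
    geometry: Polygon
    land_fraction: float

    @property
    def centroid(self) -> Point:
        return self.geometry.centroid

    def contains_point(self, x: float, y: float) -> bool:
        """Half-open containment test [x0, x1) x [y0, y1)."""
        x0, y0, x1, y1 = self.geometry.bounds
        return (x0 <= x < x1) and (y0 <= y < y1)


@dataclass
class GridSystem:
    """The retained-cell lattice: the spatial frame for the whole analysis."""

    cell_size: float
    origin: tuple[float, float]
    cells: list[GridCell] = field(default_factory=list)

    @property
    def cell_area(self) -> float:
        """Full cell area in m^2 (denominator for per-cell proportions)."""
        return self.cell_size**2

    @property
    def cell_ids(self) -> list[int]:
        return [c.id for c in self.cells]

    def __len__(self) -> int:
        return len(self.cells)

    def cell_index_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) lattice index of a point under the half-open rule."""
        ox, oy = self.origin
        return (
            int(math.floor((y - oy) / self.cell_size)),
            int(math.floor((x - ox) / self.cell_size)),
        )

    def rowcol_to_id(self) -> dict[tuple[int, int], int]:
        return {(c.row, c.col): c.id for c in self.cells}

    def frame(self) -> pd.DataFrame:
        """Cells as a DataFrame indexed by cell id."""
        return pd.DataFrame(
            {
                "row": [c.row for c in self.cells],
                "col": [c.col for c in self.cells],
                "land_fraction": [c.land_fraction for c in self.cells],
                "cx": [c.centroid.x for c in self.cells],
                "cy": [c.centroid.y for c in self.cells],
            },
            index=pd.Index(self.cell_ids, name="cell_id"),
        )

    def write_geojson(self, path: str | Path, extra: dict[int, dict] | None = None) -> None:
        feats = []
        for c in self.cells:
            props = {"id": c.id, "row": c.row, "col": c.col,
                     "land_fraction": c.land_fraction}
            if extra and c.id in extra:
                props.update(extra[c.id])
            feats.append((c.geometry, props))
        write_features(
            path,
            feats,
            metadata={"cell_size": self.cell_size, "origin": list(self.origin)},
        )

    @classmethod
    def read_geojson(cls, path: str | Path) -> "GridSystem":
        import json

        with open(path) as fh:
            obj = json.load(fh)
        meta = obj.get("metadata", {})
        feats = read_features(path)
        cells = [
            GridCell(
                id=int(p["id"]), row=int(p["row"]), col=int(p["col"]),
                geometry=g, land_fraction=float(p["land_fraction"]),
            )
            for g, p in feats
        ]
        cell_size = float(meta["cell_size"])
        origin = tuple(meta["origin"])
        return cls(cell_size=cell_size, origin=origin, cells=cells)


def _clean_polygon(geom: BaseGeometry, feature_id=None) -> BaseGeometry:
    if geom.is_valid:
        return geom
    repaired = make_valid(geom)
    if not repaired.is_valid:
        raise ValueError(f"invalid geometry could not be repaired (feature {feature_id})")
    return repaired


def build_grid(
    land_mask: BaseGeometry,
    cell_size: float,
    extent: tuple[float, float, float, float] | None = None,
    *,
    land_fraction_threshold: float = LAND_FRACTION_THRESHOLD,
) -> GridSystem:
    """Lay the square lattice over ``land_mask`` and keep mostly-land cells.

    Parameters
    ----------
    land_mask
        Polygon(al) geometry of land, planar CRS in metres.
    cell_size
        Cell edge length in metres (> 0).
    extent
        Optional (xmin, ymin, xmax, ymax) to grid over; defaults to the
        land-mask bounds.  Must cover the mask.
    land_fraction_threshold
        Cells with ``land_fraction`` below this are dropped.  The default
        0.5 keeps cells with *at least* half their area on land (closed
        lower bound).

    Returns
    -------
    GridSystem
        Retained cells with exact land fractions, ids assigned row-major
        from the south-west corner.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    land_mask = _clean_polygon(land_mask, "land_mask")
    if land_mask.is_empty:
        raise EmptyGridError("land mask is empty")
    xmin, ymin, xmax, ymax = extent if extent is not None else land_mask.bounds
    # snap origin down to a multiple of the cell size
    ox = math.floor(xmin / cell_size) * cell_size
    oy = math.floor(ymin / cell_size) * cell_size
    ncols = max(1, math.ceil((xmax - ox) / cell_size))
    nrows = max(1, math.ceil((ymax - oy) / cell_size))

    area = cell_size**2
    cells: list[GridCell] = []
    cell_id = 0
    for r in range(nrows):
        for c in range(ncols):
            geom = box(ox + c * cell_size, oy + r * cell_size,
                       ox + (c + 1) * cell_size, oy + (r + 1) * cell_size)
            frac = geom.intersection(land_mask).area / area
            if frac >= land_fraction_threshold:
                cells.append(GridCell(cell_id, r, c, geom, frac))
                cell_id += 1
    if not cells:
        raise EmptyGridError("no grid cell intersects the land mask above threshold")
    return GridSystem(cell_size=cell_size, origin=(ox, oy), cells=cells)


def overlay_nfc(
    grid: GridSystem,
    forest_polygons: list[BaseGeometry] | BaseGeometry,
    *,
    disjoint: bool = False,
) -> pd.Series:
    """Forest-cover fraction per cell by exact polygon overlay.

    NFC of a cell is area(cell ∩ forest) / area(cell), with area(cell) the
    full cell area.  Overlapping input polygons are unioned first so no
    area is double-counted; pass ``disjoint=True`` when the caller
    guarantees non-overlap (e.g. mask polygonization output) to skip the
    union and simply sum per-polygon intersections.

    Returns a float Series in [0, 1] indexed by cell id.
    """
    if isinstance(forest_polygons, BaseGeometry):
        forest_polygons = [forest_polygons]
    polys = [_clean_polygon(g, i) for i, g in enumerate(forest_polygons)]
    polys = [g for g in polys if not g.is_empty]
    nfc = pd.Series(0.0, index=pd.Index(grid.cell_ids, name="cell_id"), name="nfc")
    if not polys:
        return nfc
    if not disjoint and len(polys) > 1:
        merged = union_all(polys)
        polys = list(merged.geoms) if hasattr(merged, "geoms") else [merged]
    import shapely

    poly_arr = np.array(polys, dtype=object)
    cell_arr = np.array([c.geometry for c in grid.cells], dtype=object)
    tree = STRtree(polys)
    ci, pi = tree.query(cell_arr)
    if len(ci):
        areas = shapely.area(shapely.intersection(poly_arr[pi], cell_arr[ci]))
        covered = np.zeros(len(grid.cells))
        np.add.at(covered, ci, areas)
        nfc.iloc[:] = np.minimum(covered / grid.cell_area, 1.0)
    return nfc


def aggregate_raster(grid: GridSystem, raster: Raster) -> pd.Series:
    """Mean raster value per cell via pixel-centroid containment.

    A pixel contributes to the (single) cell whose half-open footprint
    contains its centroid; NaN pixels are ignored.  Cells containing no
    pixel centroid (or only NaN pixels) come back as NaN.
    """
    xs, ys = raster.pixel_centroids()
    vals = raster.data
    ok = ~np.isnan(vals)
    ox, oy = grid.origin
    cols = np.floor((xs[ok] - ox) / grid.cell_size).astype(int)
    rows = np.floor((ys[ok] - oy) / grid.cell_size).astype(int)
    lookup = grid.rowcol_to_id()
    frame = pd.DataFrame({"row": rows, "col": cols, "value": vals[ok]})
    frame["cell_id"] = [
        lookup.get((r, c), -1) for r, c in zip(frame["row"], frame["col"])
    ]
    frame = frame[frame["cell_id"] >= 0]
    means = frame.groupby("cell_id")["value"].mean()
    out = pd.Series(np.nan, index=pd.Index(grid.cell_ids, name="cell_id"))
    out.loc[means.index] = means
    return out


def polygonize_mask(raster: Raster, *, threshold: float = 0.5) -> list[Polygon]:
    """Convert a binary mask raster into disjoint rectangles.

    Consecutive above-threshold pixels in each row are merged into one
    rectangle; the result is an exact, non-overlapping cover of the masked
    pixels suitable for ``overlay_nfc(..., disjoint=True)``.
    """
    data = raster.data
    ny, nx = data.shape
    cs = raster.cellsize
    x0 = raster.xll
    ytop = raster.yll + ny * cs
    rects: list[Polygon] = []
    mask = np.nan_to_num(data, nan=-np.inf) >= threshold
    for r in range(ny):
        row = mask[r]
        if not row.any():
            continue
        # run-length encode the row
        diff = np.diff(row.astype(np.int8))
        starts = list(np.where(diff == 1)[0] + 1)
        ends = list(np.where(diff == -1)[0] + 1)
        if row[0]:
            starts.insert(0, 0)
        if row[-1]:
            ends.append(nx)
        y1 = ytop - r * cs
        y0 = y1 - cs
        for s, e in zip(starts, ends):
            rects.append(box(x0 + s * cs, y0, x0 + e * cs, y1))
    return rects
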