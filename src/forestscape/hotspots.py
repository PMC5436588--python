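"""Getis-Ord Gi* hot-spot statistic over the grid.

For a per-cell field x (here: forest-cover change between two periods) the
local Gi* statistic at cell i is

             sum_j w_ij x_j  -  Xbar sum_j w_ij
    Gi* = ------------------------------------------------
           S sqrt( [ n sum_j w_ij^2 - (sum_j w_ij)^2 ] / (n - 1) )

with Xbar the global mean, S = sqrt(sum_j x_j^2 / n - Xbar^2) the global
population standard deviation, and w the spatial weights *including the
self-weight* (w_ii > 0).  Gi* is already a z-score: no further scaling is
needed.  Positive values flag clusters of above-mean cells, negative values
clusters of below-mean cells; on a forest-*change* field negative clusters
are deforestation hot spots.

A constant field has S = 0 and the statistic is undefined; this module
returns an explicit undefined flag rather than silently dividing 0 by 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

from .geojson_io import write_features
from .gridding import GridSystem

__all__ = [
    "SpatialWeights",
    "GiStarField",
    "build_weights",
    "gi_star",
    "hotspot_report",
    "CLASS_LABELS",
]

#: two-sided normal quantiles for the 90 / 95 / 99 % confidence levels
Z_90, Z_95, Z_99 = 1.645, 1.960, 2.576

CLASS_LABELS = (
    "cold99", "cold95", "cold90", "not significant", "hot90", "hot95", "hot99",
)


@dataclass
class SpatialWeights:
    """Sparse symmetric binary weights over the retained cells, self included."""

    matrix: sparse.csr_matrix
    cell_ids: list[int]
    scheme: str
    parameter: float | None = None

    @property
    def n(self) -> int:
        return len(self.cell_ids)


def build_weights(
    grid: GridSystem,
    scheme: str = "queen",
    parameter: float | None = None,
) -> SpatialWeights:
    """Binary spatial weights with self-weight 1.

    Schemes
    -------
    ``queen``
        Lattice neighbours sharing any corner or edge (8-neighbourhood).
    ``rook``
        Lattice neighbours sharing an edge (4-neighbourhood).
    ``distance_band``
        Cells whose centroids lie within ``parameter`` metres.

    Cells with no neighbour under a distance band keep their self-weight
    only and trigger a warning.
    """
    n = len(grid)
    ids = grid.cell_ids
    rows: list[int] = []
    cols: list[int] = []
    if scheme in ("queen", "rook"):
        index = {(c.row, c.col): i for i, c in enumerate(grid.cells)}
        if scheme == "queen":
            offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)]
        else:
            offsets = [(0, 0), (-1, 0), (1, 0), (0, -1), (0, 1)]
        for i, cell in enumerate(grid.cells):
            for dr, dc in offsets:
                j = index.get((cell.row + dr, cell.col + dc))
                if j is not None:
                    rows.append(i)
                    cols.append(j)
    elif scheme == "distance_band":
        if parameter is None:
            raise ValueError("distance_band scheme requires a band radius (m)")
        if parameter < grid.cell_size:
            warnings.warn(
                "distance band smaller than the cell size: cells may be isolated",
                stacklevel=2,
            )
        pts = np.array([[c.centroid.x, c.centroid.y] for c in grid.cells])
        tree = cKDTree(pts)
        pairs = tree.query_pairs(parameter, output_type="ndarray")
        rows = list(pairs[:, 0]) + list(pairs[:, 1]) + list(range(n))
        cols = list(pairs[:, 1]) + list(pairs[:, 0]) + list(range(n))
        neigh = np.zeros(n, dtype=int)
        if len(pairs):
            np.add.at(neigh, pairs[:, 0], 1)
            np.add.at(neigh, pairs[:, 1], 1)
        if (neigh == 0).any():
            warnings.warn(
                f"{int((neigh == 0).sum())} isolated cell(s) under the distance "
                "band: self-only weights",
                stacklevel=2,
            )
    else:
        raise ValueError(f"unknown weights scheme {scheme!r}")
    data = np.ones(len(rows))
    matrix = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
    matrix.data[:] = 1.0  # guard against accidental duplicate entries
    return SpatialWeights(matrix=matrix, cell_ids=list(ids), scheme=scheme,
                          parameter=parameter)


@dataclass
class GiStarField:
    """Per-cell Gi* z-scores and their hot/cold classification."""

    z: pd.Series
    classes: pd.Series
    undefined: bool = False

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z": self.z, "class": self.classes})


def classify_z(z: np.ndarray) -> np.ndarray:
    """Map z-scores to the seven-level hot/cold classes."""
    out = np.full(z.shape, "not significant", dtype=object)
    out[z >= Z_90] = "hot90"
    out[z >= Z_95] = "hot95"
    out[z >= Z_99] = "hot99"
    out[z <= -Z_90] = "cold90"
    out[z <= -Z_95] = "cold95"
    out[z <= -Z_99] = "cold99"
    out[np.isnan(z)] = "undefined"
    return out


def gi_star(values: pd.Series | np.ndarray, weights: SpatialWeights) -> GiStarField:
    """Vectorized Gi* z-scores for a per-cell field.

    ``values`` must be finite and aligned with ``weights.cell_ids`` (a
    Series is re-indexed to that order).  A constant field returns NaN
    z-scores with ``undefined=True``.
    """
    idx = pd.Index(weights.cell_ids, name="cell_id")
    if isinstance(values, pd.Series):
        x = values.reindex(idx).to_numpy(dtype=float)
    else:
        x = np.asarray(values, dtype=float)
    n = weights.n
    if x.shape != (n,):
        raise ValueError("values and weights cover different index sets")
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    if n < 2:
        raise ValueError("need at least two cells")
    xbar = x.mean()
    s = np.sqrt(max((x**2).mean() - xbar**2, 0.0))
    if np.ptp(x) == 0 or s == 0:  # exactly constant field: Gi* undefined
        z = np.full(n, np.nan)
        zs = pd.Series(z, index=idx, name="z")
        return GiStarField(z=zs, classes=pd.Series(classify_z(z), index=idx),
                          undefined=True)
    w = weights.matrix
    s1 = np.asarray(w.sum(axis=1)).ravel()           # sum_j w_ij
    s2 = np.asarray(w.multiply(w).sum(axis=1)).ravel()  # sum_j w_ij^2
    num = w @ x - xbar * s1
    den = s * np.sqrt((n * s2 - s1**2) / (n - 1))
    z = num / den
    zs = pd.Series(z, index=idx, name="z")
    return GiStarField(z=zs, classes=pd.Series(classify_z(z), index=idx))


def hotspot_report(
    grid: GridSystem,
    change_field: pd.Series,
    weights: SpatialWeights,
    *,
    geojson_path: str | Path | None = None,
    field_name: str = "change",
) -> GiStarField:
    """Gi* field for a change layer, optionally written as GeoJSON.

    On a forest-change field, cold clusters (negative z) mark hot spots of
    forest *decrease* and hot clusters mark increase.
    """
    result = gi_star(change_field, weights)
    if geojson_path is not None:
        z = result.z
        cls = result.classes
        feats = [
            (
                cell.geometry,
                {
                    "id": cell.id,
                    field_name: None
                    if pd.isna(change_field.get(cell.id))
                    else float(change_field.get(cell.id)),
                    "z": None if pd.isna(z.loc[cell.id]) else float(z.loc[cell.id]),
                    "class": cls.loc[cell.id],
                },
            )
            for cell in grid.cells
        ]
        write_features(
            geojson_path, feats,
            metadata={"scheme": weights.scheme, "parameter": weights.parameter,
                      "field": field_name},
        )
    return result
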