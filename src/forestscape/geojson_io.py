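"""GeoJSON reading/writing on top of shapely geometries.

Features are represented as ``(geometry, properties)`` pairs where
``geometry`` is a shapely object and ``properties`` a plain dict.
Coordinates are in the package-wide projected planar CRS (metres).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

__all__ = ["read_features", "write_features"]


def read_features(path: str | Path) -> list[tuple[BaseGeometry, dict]]:
    """Read a GeoJSON FeatureCollection (or single Feature/geometry)."""
    with open(path) as fh:
        obj = json.load(fh)
    kind = obj.get("type")
    if kind == "FeatureCollection":
        return [
            (shape(f["geometry"]), f.get("properties") or {})
            for f in obj["features"]
        ]
    if kind == "Feature":
        return [(shape(obj["geometry"]), obj.get("properties") or {})]
    return [(shape(obj), {})]


def write_features(
    path: str | Path,
    features: Iterable[tuple[BaseGeometry, dict]],
    *,
    metadata: dict | None = None,
) -> None:
    """Write features as a GeoJSON FeatureCollection.

    ``metadata`` lands in a top-level ``"metadata"`` member (GeoJSON allows
    foreign members) and is used for run provenance.
    """
    collection: dict = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
            for geom, props in features
        ],
    }
    if metadata:
        collection["metadata"] = metadata
    with open(path, "w") as fh:
        json.dump(collection, fh)
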