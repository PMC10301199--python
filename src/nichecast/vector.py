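"""Vector layers (polygons / polylines) with GeoJSON I/O.

Geometries are shapely objects in WGS84 geographic coordinates; the
attribute table is a list of per-feature property dicts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .raster import WGS84


@dataclass
class VectorLayer:
    """Geometries plus a parallel attribute table."""

    geometries: list[BaseGeometry]
    attributes: list[dict] = field(default_factory=list)
    crs: str = WGS84

    def __post_init__(self) -> None:
        if not self.attributes:
            self.attributes = [{} for _ in self.geometries]
        if len(self.attributes) != len(self.geometries):
            raise ValueError("attributes and geometries lengths differ")
        for i, g in enumerate(self.geometries):
            if not g.is_valid:
                fixed = shapely.make_valid(g)
                if not fixed.is_valid:
                    raise ValueError(f"geometry {i} is invalid")
                self.geometries[i] = fixed

    def __len__(self) -> int:
        return len(self.geometries)

    def union(self) -> BaseGeometry:
        return shapely.unary_union(self.geometries)


def read_vector(path: str | Path) -> VectorLayer:
    """Read a GeoJSON FeatureCollection (or bare geometry) file."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in doc["features"]]
        attrs = [dict(f.get("properties") or {}) for f in doc["features"]]
    elif doc.get("type") == "Feature":
        geoms = [shape(doc["geometry"])]
        attrs = [dict(doc.get("properties") or {})]
    else:
        geoms = [shape(doc)]
        attrs = [{}]
    return VectorLayer(geoms, attrs)


def write_vector(layer: VectorLayer, path: str | Path) -> None:
    """Write a layer as a GeoJSON FeatureCollection."""
    features = [{"type": "Feature", "geometry": mapping(g), "properties": a}
                for g, a in zip(layer.geometries, layer.attributes)]
    doc = {"type": "FeatureCollection", "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh)
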