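"""Planar study regions.

All coordinates in this package are planar miles in an arbitrary local
frame: the distances a proximity-based app reports are linear, so a local
planar approximation is the natural working geometry and no geographic
projection logic is needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon, shape, mapping

from .errors import InvalidRegionError, ParseError

__all__ = ["StudyRegion"]


@dataclass(frozen=True)
class StudyRegion:
    """A polygonal analysis extent, in planar miles.

    Parameters
    ----------
    polygon : shapely.Polygon
        A valid, simple polygon with positive area.
    name : str
        Human-readable label for logs and plots.
    """

    polygon: Polygon
    name: str = "region"

    def __post_init__(self) -> None:
        if self.polygon.is_empty:
            raise InvalidRegionError("region polygon is empty")
        if not self.polygon.is_valid:
            raise InvalidRegionError("region polygon is self-intersecting or otherwise invalid")
        if self.polygon.area <= 0:
            raise InvalidRegionError("region polygon has zero area")

    @classmethod
    def from_vertices(cls, vertices, name: str = "region") -> "StudyRegion":
        """Build from an ordered vertex list; the ring is closed if needed."""
        vertices = list(vertices)
        if len(vertices) >= 2 and tuple(vertices[0]) == tuple(vertices[-1]):
            vertices = vertices[:-1]
        if len(vertices) < 3:
            raise InvalidRegionError("a polygon needs at least three distinct vertices")
        return cls(Polygon(vertices), name=name)

    @property
    def area(self) -> float:
        """Region area in square miles."""
        return self.polygon.area

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in miles."""
        return self.polygon.bounds

    def contains(self, x, y):
        """Vectorized point-in-polygon test (boundary counts as inside)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = shapely.contains_xy(self.polygon, x, y)
        on_edge = shapely.intersects_xy(self.polygon.boundary, x, y)
        return inside | on_edge

    # -- GeoJSON round-trip (coordinates interpreted as planar miles) -------

    @classmethod
    def from_geojson(cls, path, name: str | None = None) -> "StudyRegion":
        with open(path) as fh:
            try:
                obj = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}: invalid JSON at line {exc.lineno}") from exc
        geom = obj
        label = name
        if obj.get("type") == "Feature":
            label = label or obj.get("properties", {}).get("name")
            geom = obj["geometry"]
        if geom.get("type") != "Polygon":
            raise ParseError(f"{path}: expected a GeoJSON Polygon, got {geom.get('type')!r}")
        return cls(shape(geom), name=label or "region")

    def to_geojson(self, path) -> None:
        feature = {
            "type": "Feature",
            "properties": {"name": self.name},
            "geometry": mapping(self.polygon),
        }
        with open(path, "w") as fh:
            json.dump(feature, fh, indent=1)
            fh.write("\n")
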