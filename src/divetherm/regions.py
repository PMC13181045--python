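"""Adriatic sub-region polygons for spatial stratification.

The four sub-regions are the Western Adriatic Coastal Current band (WACC,
a coastal strip along the Italian coast from the Po Delta to the Strait of
Otranto) and the northern (NA), middle (MA) and southern (SA) Adriatic basins.
Their published definitions rest on bathymetry and named transects that cannot
be reproduced exactly from text, so the shipped polygons are documented
approximations (the NA bathymetric boundary is replaced by a fixed-latitude
chord; the WACC band is a buffered coastal polyline). They live in an editable
GeoJSON file so users can substitute their own boundaries.

Assignment is point-in-polygon with the priority order WACC > NA > MA > SA;
points outside every polygon (e.g. the northern Ionian Sea) map to "other".
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

from shapely.geometry import Point, shape
from shapely.geometry.base import BaseGeometry

#: Evaluation order: the coastal band takes precedence over the basins.
PRIORITY = ("WACC", "NA", "MA", "SA")

OTHER = "other"

DEFAULT_REGIONS_RESOURCE = "adriatic_regions.geojson"


class RegionSet:
    """Named simple polygons with a fixed priority order."""

    def __init__(self, polygons: dict[str, BaseGeometry]):
        missing = [n for n in PRIORITY if n not in polygons]
        if missing:
            raise ValueError(f"regions missing: {missing}")
        for name, poly in polygons.items():
            if not poly.is_valid:
                raise ValueError(f"region {name!r} polygon is invalid (self-intersecting?)")
        self.polygons = polygons

    def assign(self, lat: float, lon: float) -> str:
        """Sub-region containing (lat, lon), or "other"; boundaries inclusive."""
        pt = Point(lon, lat)
        for name in PRIORITY:
            if self.polygons[name].covers(pt):
                return name
        return OTHER

    @classmethod
    def from_geojson(cls, path: str | Path) -> "RegionSet":
        with open(path) as fh:
            gj = json.load(fh)
        return cls._from_featurecollection(gj)

    @classmethod
    def _from_featurecollection(cls, gj: dict) -> "RegionSet":
        polys = {}
        for feat in gj.get("features", []):
            name = feat.get("properties", {}).get("name")
            if name is None:
                raise ValueError("regions GeoJSON feature lacks a 'name' property")
            polys[name] = shape(feat["geometry"])
        return cls(polys)

    @classmethod
    def default(cls) -> "RegionSet":
        text = (resources.files("divetherm") / "data" / DEFAULT_REGIONS_RESOURCE).read_text()
        return cls._from_featurecollection(json.loads(text))

    def to_geojson(self, path: str | Path) -> None:
        from shapely.geometry import mapping

        feats = [
            {"type": "Feature", "properties": {"name": n}, "geometry": mapping(p)}
            for n, p in self.polygons.items()
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh, indent=1)
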