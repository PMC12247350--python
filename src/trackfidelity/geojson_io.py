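"""Minimal GeoJSON writing (WGS84, lon-lat order) via shapely + stdlib json."""

from __future__ import annotations

import json

from shapely.geometry import mapping


def feature(geom, properties: dict | None = None) -> dict:
    return {"type": "Feature", "geometry": mapping(geom),
            "properties": properties or {}}


def linestring_feature(coords, properties: dict | None = None) -> dict:
    return {"type": "Feature",
            "geometry": {"type": "LineString",
                         "coordinates": [[float(x), float(y)] for x, y in coords]},
            "properties": properties or {}}


def write_collection(features: list[dict], path) -> None:
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_polygons(path):
    """Read the polygons of a GeoJSON file; returns list of (shapely geom, properties)."""
    from shapely.geometry import shape
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    out = []
    for f in feats:
        geom = shape(f["geometry"] if f.get("type") == "Feature" else f)
        out.append((geom, f.get("properties", {})))
    return out
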