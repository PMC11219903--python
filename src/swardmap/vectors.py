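"""GeoJSON-backed vector layer I/O.

Vector layers are passed around as lists of feature dicts:
``{"geometry": <shapely geometry>, <property>: <value>, ...}`` and persisted
as GeoJSON FeatureCollections (plain text, GIS-interoperable).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import shapely
from shapely.geometry import mapping, shape

Feature = dict[str, Any]


def write_geojson(features: list[Feature], path: str | Path) -> Path:
    path = Path(path)
    out = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(f["geometry"]),
                "properties": {k: v for k, v in f.items() if k != "geometry"},
            }
            for f in features
        ],
    }
    path.write_text(json.dumps(out))
    return path


def read_geojson(path: str | Path) -> list[Feature]:
    doc = json.loads(Path(path).read_text())
    feats: list[Feature] = []
    for f in doc["features"]:
        rec: Feature = {"geometry": shape(f["geometry"])}
        rec.update(f.get("properties") or {})
        feats.append(rec)
    return feats


def geoms(features: list[Feature]) -> list[shapely.Geometry]:
    return [f["geometry"] for f in features]
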