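"""GeoJSON line-feature I/O (projected coordinates, metres)."""

from __future__ import annotations

import json
from pathlib import Path

from shapely.geometry import LineString, mapping, shape

__all__ = ["write_lines_geojson", "read_lines_geojson"]


def write_lines_geojson(lines: list[LineString], path: str | Path,
                        properties: dict | None = None) -> None:
    feats = [{"type": "Feature", "properties": dict(properties or {}),
              "geometry": mapping(line)} for line in lines]
    fc = {"type": "FeatureCollection", "features": feats}
    Path(path).write_text(json.dumps(fc))


def read_lines_geojson(path: str | Path) -> list[LineString]:
    fc = json.loads(Path(path).read_text())
    lines = []
    for feat in fc.get("features", []):
        geom = shape(feat["geometry"])
        if geom.geom_type == "LineString":
            lines.append(geom)
        elif geom.geom_type == "MultiLineString":
            lines.extend(geom.geoms)
    return lines
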