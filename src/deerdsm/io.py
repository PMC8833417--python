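"""Plain-text artifact IO: CSV tables, GeoJSON vectors, ASCII rasters.

Everything the pipeline writes is inspectable text; planar metre
coordinates are used throughout (synthetic world, no CRS).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .synthetic import TransectRecord

__all__ = [
    "write_transects_geojson",
    "read_transects_geojson",
    "write_districts_geojson",
    "write_effects_yaml",
]


def write_transects_geojson(transects: list[TransectRecord], path: str | Path) -> None:
    features = [{
        "type": "Feature",
        "geometry": {"type": "LineString",
                     "coordinates": [[t.x0, t.y0], [t.x1, t.y1]]},
        "properties": {"id": t.id, "quadrant": t.quadrant, "length_m": t.length,
                       "design": t.design, "stratum": t.stratum},
    } for t in transects]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}, indent=1))


def read_transects_geojson(path: str | Path) -> list[TransectRecord]:
    data = json.loads(Path(path).read_text())
    out = []
    for f in data["features"]:
        (x0, y0), (x1, y1) = f["geometry"]["coordinates"]
        p = f["properties"]
        out.append(TransectRecord(
            id=p["id"], quadrant=p["quadrant"], x0=x0, y0=y0, x1=x1, y1=y1,
            length=p["length_m"], design=p["design"], stratum=p["stratum"],
        ))
    return out


def write_districts_geojson(polygons: dict[str, list[tuple[float, float]]],
                            properties: pd.DataFrame, path: str | Path) -> None:
    """Districts as GeoJSON polygons with id + harvest_density properties."""
    features = []
    for did, ring in polygons.items():
        props = {"id": did}
        if did in properties.index:
            props.update({k: float(v) for k, v in properties.loc[did].items()})
        features.append({
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [[list(p) for p in ring]]},
            "properties": props,
        })
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}, indent=1))


def write_effects_yaml(truth, path: str | Path) -> None:
    import yaml

    spec = {
        "intercept": float(truth.intercept),
        "effects": [{
            "covariate": e.covariate, "form": e.form, "amplitude": float(e.amplitude),
            "center": float(e.center), "scale": float(e.scale),
        } for e in truth.effects],
    }
    Path(path).write_text(yaml.safe_dump(spec, sort_keys=False))
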