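"""GeoJSON-based vector I/O.

Layers are written as one GeoJSON FeatureCollection per class (plain text,
widely readable). The CRS label travels in a top-level ``crs_id`` member.
"""

from __future__ import annotations

import json
from pathlib import Path

import shapely
from shapely.geometry import shape

from .vectorize import VectorLayerSet

__all__ = ["write_layerset", "read_layerset"]


def _collection(geoms, crs_id: str) -> dict:
    return {
        "type": "FeatureCollection",
        "crs_id": crs_id,
        "features": [
            {
                "type": "Feature",
                "properties": {"fid": i},
                "geometry": json.loads(shapely.to_geojson(g)),
            }
            for i, g in enumerate(geoms)
        ],
    }


def write_layerset(layers: VectorLayerSet, directory: str | Path) -> dict[str, Path]:
    """Write one ``<epoch>_<class>.geojson`` file per layer; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, geoms in {**layers.polygons, **layers.lines}.items():
        path = directory / f"{layers.epoch}_{name}.geojson"
        path.write_text(json.dumps(_collection(geoms, layers.crs_id)))
        paths[name] = path
    return paths


def read_layerset(directory: str | Path, epoch: str) -> VectorLayerSet:
    directory = Path(directory)
    polygons, lines = {}, {}
    crs_id = "local"
    for path in sorted(directory.glob(f"{epoch}_*.geojson")):
        name = path.stem[len(epoch) + 1 :]
        doc = json.loads(path.read_text())
        crs_id = doc.get("crs_id", crs_id)
        geoms = [shape(f["geometry"]) for f in doc["features"]]
        if geoms and geoms[0].geom_type in ("LineString", "MultiLineString"):
            lines[name] = geoms
        else:
            polygons[name] = geoms
    return VectorLayerSet(epoch=epoch, polygons=polygons, lines=lines,
                          crs_id=crs_id)
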