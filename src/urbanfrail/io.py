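"""File formats: GeoJSON facility bundles, ESRI ASCII rasters, cohort CSV,
provenance records.

A "city bundle" is a directory with ``grid.json`` (grid geometry and cluster
seeds) and one ``facility_<type>.geojson`` point layer per facility type.
Rasters are exchanged as ESRI ASCII grids, a plain-text format readable by
any GIS. Round trips are lossless to well below 1e-9 m.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import shape

from .facilities import DEFAULT_BANDS, FacilityLayer, FacilityType
from .grid import GridSpec, RasterField

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# GeoJSON facility layers


def layer_to_geojson(layer: FacilityLayer) -> dict:
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
                "properties": {"facility_type": layer.facility_type.value},
            }
            for x, y in layer.points
        ],
    }


def layer_from_geojson(doc: dict, bands=None) -> FacilityLayer:
    feats = doc.get("features", [])
    pts, ftypes = [], set()
    for i, feat in enumerate(feats):
        geom = shape(feat["geometry"])
        if geom.geom_type != "Point":
            raise ValueError(f"feature {i}: expected Point geometry, got {geom.geom_type}")
        ft = feat.get("properties", {}).get("facility_type")
        try:
            ftypes.add(FacilityType(ft))
        except ValueError:
            raise ValueError(f"feature {i}: unknown facility_type {ft!r}") from None
        pts.append((geom.x, geom.y))
    if len(ftypes) != 1:
        raise ValueError(f"layer must hold exactly one facility type, got {sorted(t.value for t in ftypes)}")
    ftype = ftypes.pop()
    return FacilityLayer(ftype, np.asarray(pts), bands or DEFAULT_BANDS[ftype])


def write_city_bundle(path, grid: GridSpec, layers: dict[FacilityType, FacilityLayer],
                      cluster_raster: np.ndarray | None = None) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "grid.json").write_text(json.dumps(asdict(grid), indent=1) + "\n")
    for ftype, layer in layers.items():
        doc = layer_to_geojson(layer)
        (path / f"facility_{ftype.value}.geojson").write_text(json.dumps(doc) + "\n")
    if cluster_raster is not None:
        write_ascii_grid(path / "clusters.asc", None, grid=grid, values=cluster_raster)


def read_city_bundle(path) -> tuple[GridSpec, dict[FacilityType, FacilityLayer]]:
    path = Path(path)
    grid = GridSpec(**json.loads((path / "grid.json").read_text()))
    layers: dict[FacilityType, FacilityLayer] = {}
    for f in sorted(path.glob("facility_*.geojson")):
        layer = layer_from_geojson(json.loads(f.read_text()))
        layers[layer.facility_type] = layer
    if not layers:
        raise ValueError(f"no facility layers found in {path}")
    missing = [t.value for t in FacilityType if t not in layers]
    if missing:
        logger.warning(
            "missing facility layer(s) %s: summary index bounds become [%d, %d]",
            missing, len(layers), 3 * len(layers),
        )
    return grid, layers


# ---------------------------------------------------------------------------
# ESRI ASCII rasters


def write_ascii_grid(path, raster: RasterField | None, grid: GridSpec | None = None,
                     values: np.ndarray | None = None, nodata: float = -9999) -> None:
    """Write an ESRI ASCII grid (rows written north to south)."""
    if raster is not None and values is None:
        grid, values = raster.grid, raster.values
    lines = [
        f"ncols {grid.n_cols}",
        f"nrows {grid.n_rows}",
        f"xllcorner {grid.origin_x!r}",
        f"yllcorner {grid.origin_y!r}",
        f"cellsize {grid.cell_size!r}",
        f"NODATA_value {nodata}",
    ]
    for row in values[::-1]:
        lines.append(" ".join(repr(float(v)) if not float(v).is_integer() else str(int(v))
                              for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_ascii_grid(path, kind: str = "distance", n_layers: int = 1) -> RasterField:
    text = Path(path).read_text().splitlines()
    header = {}
    for line in text[:6]:
        k, v = line.split()
        header[k.lower()] = float(v)
    grid = GridSpec(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell_size=header["cellsize"],
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
    )
    values = np.array([[float(v) for v in line.split()] for line in text[6:] if line.strip()])
    return RasterField(grid, values[::-1], kind=kind, n_layers=n_layers)


# ---------------------------------------------------------------------------
# cohort CSV and provenance


def write_cohort_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_provenance(path, record: dict) -> None:
    Path(path).write_text(json.dumps(record, indent=1, sort_keys=True, default=str) + "\n")
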