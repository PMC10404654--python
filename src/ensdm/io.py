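"""Plain-text geospatial I/O.

Rasters are exchanged as ESRI ASCII grids (``.asc``) — one file per layer
with a shared header — and vectors as GeoJSON. Both are text formats readable
by any GIS.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import mapping, shape

from .grid import GridSpec, PredictorStack, Raster

_NODATA = -9999.0


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write a raster as an ESRI ASCII grid (cell-corner referenced header)."""
    g = raster.grid
    vals = np.where(raster.mask, raster.values, _NODATA)
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {g.x0}\n"
        f"yllcorner {g.y0 - g.n_rows * g.cell_size_km}\n"
        f"cellsize {g.cell_size_km}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.6g")


def read_ascii_grid(path: str | Path, crs: str = "synthetic-km") -> Raster:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    cs = header["cellsize"]
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size_km=cs,
        x0=header["xllcorner"],
        y0=header["yllcorner"] + n_rows * cs,
        crs=crs,
    )
    vals = vals.reshape(n_rows, n_cols)
    mask = vals != header["nodata_value"]
    return Raster(vals, grid, mask, Path(path).stem)


def write_stack(stack: PredictorStack, directory: str | Path) -> None:
    """One ``.asc`` per layer plus a JSON manifest of layer roles."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in stack.names:
        write_ascii_grid(stack.raster(name), directory / f"{name}.asc")
    manifest = {
        "layers": stack.names,
        "categorical": sorted(stack.categorical),
        "crs": stack.grid.crs,
        "meta": {k: v for k, v in stack.meta.items() if _json_safe(v)},
    }
    (directory / "stack.json").write_text(json.dumps(manifest, indent=2))


def read_stack(directory: str | Path) -> PredictorStack:
    directory = Path(directory)
    manifest = json.loads((directory / "stack.json").read_text())
    rasters = [
        read_ascii_grid(directory / f"{name}.asc", crs=manifest["crs"])
        for name in manifest["layers"]
    ]
    grid = rasters[0].grid
    mask = np.ones(grid.shape, dtype=bool)
    for r in rasters:
        mask &= r.mask
    stack = PredictorStack(grid=grid, mask=mask, meta=manifest.get("meta", {}))
    for r, name in zip(rasters, manifest["layers"]):
        stack.add(name, r.values, categorical=name in set(manifest["categorical"]))
    return stack


def write_geojson(geometries, path: str | Path, properties: list[dict] | None = None) -> None:
    """Write shapely geometries as a GeoJSON FeatureCollection."""
    geometries = list(geometries)
    if properties is None:
        properties = [{} for _ in geometries]
    features = [
        {"type": "Feature", "geometry": mapping(geom), "properties": props}
        for geom, props in zip(geometries, properties)
    ]
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload))


def read_geojson(path: str | Path) -> tuple[list, list[dict]]:
    """Read a GeoJSON FeatureCollection into (geometries, properties)."""
    payload = json.loads(Path(path).read_text())
    if payload.get("type") == "FeatureCollection":
        feats = payload["features"]
    elif payload.get("type") == "Feature":
        feats = [payload]
    else:  # bare geometry
        return [shape(payload)], [{}]
    geoms = [shape(f["geometry"]) for f in feats]
    props = [f.get("properties") or {} for f in feats]
    return geoms, props


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
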