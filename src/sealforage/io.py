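"""Plain-text serialization: CSV tables, ESRI ASCII grids, GeoJSON vectors.

Column dictionary of the core tables
------------------------------------
fixes.csv     seal, time (ISO 8601), x, y             (km in planar mode, lon/lat otherwise)
dives.csv     seal, dive_id, start, end, duration_s, max_depth_m, t1..t9 (s), d1..d9 (m)
wetdry.csv    seal, time, dry (1 = dry)
truth.csv     dive_id, foraging_true, x_true, y_true, trip
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "write_geojson",
    "write_sim_output",
    "sha256_of",
]


def write_ascii_grid(path, raster: np.ndarray, cell: float, x0: float, y0: float,
                     nodata: float = -9999.0) -> None:
    """ESRI ASCII grid; row order flipped so row 0 of the array is the south edge."""
    ny, nx = raster.shape
    out = np.where(np.isfinite(raster), raster, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {nx}\nnrows {ny}\nxllcorner {x0}\nyllcorner {y0}\n"
                 f"cellsize {cell}\nNODATA_value {nodata}\n")
        for row in out[::-1]:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, float, float, float]:
    """Returns (array with row 0 = south, cellsize, x0, y0); NODATA -> NaN."""
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            k, v = fh.readline().split()
            hdr[k.lower()] = float(v)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)[::-1]
    nodata = hdr.get("nodata_value", -9999.0)
    data = np.where(data == nodata, np.nan, data)
    return data, hdr["cellsize"], hdr["xllcorner"], hdr["yllcorner"]


def write_geojson(path, geometries: dict) -> None:
    """Write named shapely geometries as a GeoJSON FeatureCollection."""
    feats = [
        {"type": "Feature", "properties": {"name": name}, "geometry": mapping(geom)}
        for name, geom in geometries.items()
        if geom is not None and not getattr(geom, "is_empty", False)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def write_sim_output(sim, outdir) -> dict:
    """Serialize a SimOutput to CSV/ASCII-grid/GeoJSON files; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("fixes", sim.fixes), ("dives", sim.dives),
                     ("wetdry", sim.wetdry), ("truth", sim.truth),
                     ("haulout_truth", sim.haulout_truth),
                     ("haulouts", sim.seascape.haulouts)):
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    sc = sim.seascape
    for name, ras in (("bathy", sc.bathy), ("tidal", sc.tidal),
                      ("sediment", sc.sediment.astype(float)),
                      ("land", sc.land.astype(float)),
                      ("true_surface", sim.surface)):
        p = outdir / f"{name}.asc"
        write_ascii_grid(p, ras, sc.cell_km, sc.x0, sc.y0)
        paths[name] = p
    p = outdir / "vectors.geojson"
    write_geojson(p, {"shelf": sc.shelf_polygon, "land": sc.land_polygon,
                      "coastline": sc.coastline})
    paths["vectors"] = p
    return paths


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
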