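"""Readers and writers for the pipeline's text interchange formats.

Trees travel as Newick (see :mod:`latdiv.trees`); occurrences, tip
statistics, paleo curves and cell tables as tab-delimited text; climate
rasters as ESRI ASCII grids (one per variable); polygons as GeoJSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .simulate import ClimateField

__all__ = [
    "write_occurrences", "read_occurrences",
    "write_climate_field", "read_climate_field",
    "write_polygons", "read_polygons",
    "write_ascii_grid", "read_ascii_grid",
]


def write_occurrences(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_occurrences(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"species", "lon", "lat"}
    if not required <= set(df.columns):
        raise ValueError(f"occurrence file must have columns {sorted(required)}")
    return df


def write_ascii_grid(
    arr: np.ndarray, path: str | Path, cell_deg: float, nodata: float = -9999.0
) -> None:
    """One-band ESRI ASCII grid; row 0 is the northernmost row, global
    extent anchored at (-180, -90)."""
    nrow, ncol = arr.shape
    header = (
        f"ncols {ncol}\nnrows {nrow}\nxllcorner -180\nyllcorner {90 - nrow * cell_deg:g}\n"
        f"cellsize {cell_deg:g}\nNODATA_value {nodata:g}\n"
    )
    body = "\n".join(
        " ".join(format(v, ".8g") for v in np.where(np.isfinite(row), row, nodata))
        for row in arr
    )
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float, float]:
    """Returns (array, cellsize, nodata). Nodata cells become NaN."""
    lines = Path(path).read_text().splitlines()
    header = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
    ):
        k, v = lines[i].split()
        header[k.lower()] = float(v)
        i += 1
    arr = np.loadtxt(lines[i:])
    arr = arr.reshape(int(header["nrows"]), int(header["ncols"]))
    nodata = header.get("nodata_value", -9999.0)
    arr = np.where(arr == nodata, np.nan, arr)
    return arr, header["cellsize"], nodata


def write_climate_field(field: ClimateField, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for var in ("mat", "mtwm", "mtdq"):
        write_ascii_grid(getattr(field, var), directory / f"{var}.asc",
                         field.cell_deg, field.nodata)


def read_climate_field(directory: str | Path) -> ClimateField:
    directory = Path(directory)
    grids = {}
    cell = None
    for var in ("mat", "mtwm", "mtdq"):
        arr, cell, _ = read_ascii_grid(directory / f"{var}.asc")
        grids[var] = arr
    return ClimateField(cell_deg=cell, **grids)


def write_polygons(polys: dict, path: str | Path) -> None:
    """Named polygons as a GeoJSON FeatureCollection."""
    features = [
        {
            "type": "Feature",
            "properties": {"name": name},
            "geometry": mapping(geom),
        }
        for name, geom in polys.items()
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_polygons(path: str | Path) -> dict:
    gj = json.loads(Path(path).read_text())
    return {
        feat["properties"].get("name", str(i)): shape(feat["geometry"])
        for i, feat in enumerate(gj["features"])
    }
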