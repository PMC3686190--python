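"""Raster and table I/O: ESRI ASCII grids, stack manifests, occurrence CSVs.

Rasters are stored as ESRI ASCII grids (plain text), one file per layer,
with NaN mapped to the declared nodata value.  A multi-layer stack is a
directory of ``.asc`` files plus a ``manifest.json`` recording layer order,
kinds and cell size.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .layers import EnvStack
from .synthetic import OCCURRENCE_COLUMNS

NODATA = -9999.0


class IOError_(ValueError):
    pass


def write_raster(grid: np.ndarray, path, cell_km: float = 1.0,
                 nodata: float = NODATA, xll: float = 0.0, yll: float = 0.0) -> None:
    """Write a 2-D grid as an ESRI ASCII raster (NaN -> nodata)."""
    g = np.asarray(grid, dtype=float)
    if g.ndim != 2:
        raise IOError_("raster must be 2-D")
    out = np.where(np.isfinite(g), g, nodata)
    header = (f"ncols {g.shape[1]}\nnrows {g.shape[0]}\n"
              f"xllcorner {xll}\nyllcorner {yll}\n"
              f"cellsize {cell_km}\nNODATA_value {nodata}\n")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_raster(path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII raster; nodata cells become NaN.

    Returns (grid, metadata) with metadata keys ncols, nrows, cellsize,
    nodata_value, xllcorner, yllcorner.
    """
    meta: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value"):
            meta[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    grid = np.loadtxt(lines[i:], dtype=float)
    grid = np.atleast_2d(grid)
    nr, nc = int(meta.get("nrows", grid.shape[0])), int(meta.get("ncols", grid.shape[1]))
    if grid.shape != (nr, nc):
        raise IOError_(f"raster shape {grid.shape} != header ({nr}, {nc})")
    nodata = meta.get("nodata_value")
    if nodata is not None:
        grid = np.where(grid == nodata, np.nan, grid)
    return grid, meta


def write_stack(stack: EnvStack, directory) -> None:
    """Write a stack as one .asc per layer plus a manifest.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, grid in stack.layers.items():
        g = grid.copy()
        g[stack.nodata_mask] = np.nan
        write_raster(g, directory / f"{name}.asc", cell_km=stack.cell_km)
    manifest = {
        "layers": stack.names,
        "layer_kinds": stack.layer_kinds,
        "cell_km": stack.cell_km,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_stack(directory) -> EnvStack:
    """Read a stack written by :func:`write_stack`."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    layers: dict[str, np.ndarray] = {}
    mask = None
    for name in manifest["layers"]:
        grid, meta = read_raster(directory / f"{name}.asc")
        layers[name] = grid
        m = ~np.isfinite(grid)
        mask = m if mask is None else (mask & m)
    nodata_mask = np.zeros(next(iter(layers.values())).shape, dtype=bool)
    # a cell is nodata when every layer is missing there (study-area mask);
    # per-layer gaps remain NaN and are dropped at extraction
    if mask is not None:
        nodata_mask = mask
    return EnvStack(layers=layers, nodata_mask=nodata_mask,
                    cell_km=float(manifest["cell_km"]),
                    layer_kinds=dict(manifest["layer_kinds"]))


def write_occurrences(table: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, columns=OCCURRENCE_COLUMNS)


def read_occurrences(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in OCCURRENCE_COLUMNS if c not in df.columns]
    if missing:
        raise IOError_(f"occurrence CSV missing columns {missing}")
    return df
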