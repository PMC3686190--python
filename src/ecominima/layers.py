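"""Environmental raster stacks and the variable-extraction operators.

Turns aligned rasters plus occurrence points into the n x p variable table
used by the niche model: circular-window landscape summaries (fraction of
land cover, linear-feature density), point sampling, and terrain derivatives
(slope, aspect, vector ruggedness).

Conventions
-----------
Grids are 2-D numpy arrays indexed (row, col); row 0 is the northern edge,
so "east" is +col and "north" is -row.  Cell centers sit at
(row + 0.5, col + 0.5) * cell_km.  Circular windows contain every cell whose
center-to-center distance is <= the radius (ties included), which makes the
5-km window on a 1-km grid the classic 81-cell disc.  Windows truncate at
the grid edge and at nodata: focal means are taken over the cells actually
available, mirroring GIS focal-statistics defaults.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger("ecominima")

LAYER_KINDS = ("fraction", "density_length", "continuous")


class LayerError(ValueError):
    """Unknown layer, wrong kind, or mismatched grids."""


@dataclass
class EnvStack:
    """Aligned multi-layer environmental raster.

    Parameters
    ----------
    layers
        Mapping of layer name -> 2-D float array, all the same shape.
    nodata_mask
        Boolean grid, True where the cell is outside the study area.
    cell_km
        Cell edge length in km.
    layer_kinds
        Per-layer kind: ``fraction`` (values in [0, 1]), ``density_length``
        (km of linear feature contained in the cell) or ``continuous``.
    """

    layers: dict[str, np.ndarray]
    nodata_mask: np.ndarray
    cell_km: float
    layer_kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.layers:
            raise LayerError("EnvStack needs at least one layer")
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) != 1 or self.nodata_mask.shape not in shapes:
            raise LayerError(f"layers/mask shapes differ: {shapes}")
        if self.cell_km <= 0:
            raise LayerError("cell_km must be positive")
        for name in self.layers:
            kind = self.layer_kinds.setdefault(name, "continuous")
            if kind not in LAYER_KINDS:
                raise LayerError(f"unknown layer kind {kind!r} for {name!r}")
            if kind == "fraction":
                vals = self.layers[name][~self.nodata_mask]
                if vals.size and (vals.min() < -1e-9 or vals.max() > 1 + 1e-9):
                    raise LayerError(f"fraction layer {name!r} outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.nodata_mask.shape

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def layer(self, name: str) -> np.ndarray:
        try:
            return self.layers[name]
        except KeyError:
            raise LayerError(f"no layer named {name!r}") from None


@dataclass
class VariableTable:
    """One row per occurrence, p named environmental variables.

    ``provenance`` records (layer, summary, radius_km) per column so the
    table can be rebuilt on a new raster stack.
    """

    data: pd.DataFrame
    provenance: dict[str, tuple[str, str, float]]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise LayerError("VariableTable contains missing values")

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# circular windows and focal statistics
# ---------------------------------------------------------------------------

def circular_window(radius_km: float, cell_km: float) -> list[tuple[int, int]]:
    """Offsets (dr, dc) with center-to-center distance <= radius_km.

    Always contains (0, 0); a 5-km radius on a 1-km grid gives 81 offsets.
    """
    if radius_km < 0:
        raise LayerError("radius_km must be >= 0")
    if cell_km <= 0:
        raise LayerError("cell_km must be > 0")
    r_cells = radius_km / cell_km
    n = int(np.floor(r_cells + 1e-12))
    out = []
    for dr in range(-n, n + 1):
        for dc in range(-n, n + 1):
            if dr * dr + dc * dc <= r_cells * r_cells + 1e-12:
                out.append((dr, dc))
    return out


def _footprint(radius_km: float, cell_km: float) -> np.ndarray:
    offs = circular_window(radius_km, cell_km)
    n = max(max(abs(dr), abs(dc)) for dr, dc in offs)
    fp = np.zeros((2 * n + 1, 2 * n + 1), dtype=float)
    for dr, dc in offs:
        fp[dr + n, dc + n] = 1.0
    return fp


def _focal_sum_and_count(values: np.ndarray, valid: np.ndarray,
                         fp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Windowed sum of values over valid cells, and valid-cell count.

    Edge cells see a truncated window (constant-0 padding on both the data
    and the validity grid).
    """
    v = np.where(valid, values, 0.0)
    s = ndimage.convolve(v, fp, mode="constant", cval=0.0)
    c = ndimage.convolve(valid.astype(float), fp, mode="constant", cval=0.0)
    return s, np.rint(c)


def focal_fraction(stack: EnvStack, layer: str, radius_km: float) -> np.ndarray:
    """Mean of a fraction layer over the circular window around each cell.

    Output is nodata (NaN) where the center cell is nodata; elsewhere the
    mean is over the in-window, in-grid, non-nodata cells.
    """
    vals = stack.layer(layer)
    if stack.layer_kinds[layer] == "density_length":
        raise LayerError(f"layer {layer!r} is a density layer; use focal_density")
    fp = _footprint(radius_km, stack.cell_km)
    valid = ~stack.nodata_mask
    s, c = _focal_sum_and_count(vals, valid, fp)
    out = np.full(vals.shape, np.nan)
    ok = valid & (c > 0)
    out[ok] = s[ok] / c[ok]
    return out


def focal_density(stack: EnvStack, layer: str, radius_km: float) -> np.ndarray:
    """Linear-feature density (km/km^2) in the window around each cell.

    Sum of feature length (km) over available window cells divided by the
    area of those cells (count * cell_km^2).
    """
    vals = stack.layer(layer)
    if stack.layer_kinds[layer] != "density_length":
        raise LayerError(f"layer {layer!r} is not a density_length layer")
    fp = _footprint(radius_km, stack.cell_km)
    valid = ~stack.nodata_mask
    s, c = _focal_sum_and_count(vals, valid, fp)
    out = np.full(vals.shape, np.nan)
    ok = valid & (c > 0)
    out[ok] = s[ok] / (c[ok] * stack.cell_km ** 2)
    return out


# ---------------------------------------------------------------------------
# terrain derivatives
# ---------------------------------------------------------------------------

def _horn_gradients(dem: np.ndarray, cell_km: float) -> tuple[np.ndarray, np.ndarray]:
    """dz/dx (eastward) and dz/dy (northward) by the Horn 3x3 stencil.

    DEM values and cell size share the same length unit.  Rows increase
    southward, so the northward derivative is the negative row derivative.
    Edge rows/cols use replicated (nearest) padding.
    """
    if dem.shape[0] < 3 or dem.shape[1] < 3:
        raise LayerError("DEM must be at least 3x3")
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
    dzdx = ndimage.correlate(dem, kx, mode="nearest") / (8.0 * cell_km)
    dzdy_south = ndimage.correlate(dem, kx.T, mode="nearest") / (8.0 * cell_km)
    return dzdx, -dzdy_south


def slope_deg(dem: np.ndarray, cell_km: float) -> np.ndarray:
    """Slope in degrees from a DEM (values in km) via Horn finite differences."""
    dzdx, dzdy = _horn_gradients(np.asarray(dem, dtype=float), cell_km)
    return np.degrees(np.arctan(np.hypot(dzdx, dzdy)))


def aspect_deg(dem: np.ndarray, cell_km: float) -> np.ndarray:
    """Downslope azimuth in degrees clockwise from north; NaN on flat cells."""
    dzdx, dzdy = _horn_gradients(np.asarray(dem, dtype=float), cell_km)
    flat = (dzdx == 0) & (dzdy == 0)
    az = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    az[flat] = np.nan
    return az


def vrm(slope: np.ndarray, aspect: np.ndarray, window_cells: int = 3) -> np.ndarray:
    """Vector ruggedness measure: 1 - |resultant of unit normals| / n.

    Unit surface normals are (sin(slope)sin(aspect), sin(slope)cos(aspect),
    cos(slope)); on flat cells (aspect undefined) the normal is the vertical
    (0, 0, 1), which the formula gives in the limit slope -> 0.  Values lie
    in [0, 1]: 0 means all window normals are parallel.
    """
    slope = np.asarray(slope, dtype=float)
    aspect = np.asarray(aspect, dtype=float)
    if slope.shape != aspect.shape:
        raise LayerError("slope and aspect grids differ in shape")
    if window_cells < 3 or window_cells % 2 == 0:
        raise LayerError("window_cells must be odd and >= 3")
    theta = np.radians(slope)
    alpha = np.radians(np.where(np.isnan(aspect), 0.0, aspect))
    x = np.sin(theta) * np.sin(alpha)
    y = np.sin(theta) * np.cos(alpha)
    z = np.cos(theta)
    fp = np.ones((window_cells, window_cells))
    sx = ndimage.convolve(x, fp, mode="nearest")
    sy = ndimage.convolve(y, fp, mode="nearest")
    sz = ndimage.convolve(z, fp, mode="nearest")
    n = float(window_cells * window_cells)
    out = 1.0 - np.sqrt(sx ** 2 + sy ** 2 + sz ** 2) / n
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# table extraction
# ---------------------------------------------------------------------------

def build_variable_grids(
    stack: EnvStack,
    spec: dict[str, tuple[str, str, float]],
) -> dict[str, np.ndarray]:
    """Precompute one grid per variable from a (layer, summary, radius_km) spec.

    ``summary`` is one of ``point`` (read the cell), ``fraction`` (circular
    focal mean) or ``density`` (circular focal density).
    """
    grids: dict[str, np.ndarray] = {}
    for var, (layer, summary, radius_km) in spec.items():
        if summary == "point":
            g = stack.layer(layer).astype(float).copy()
            g[stack.nodata_mask] = np.nan
        elif summary == "fraction":
            g = focal_fraction(stack, layer, radius_km)
        elif summary == "density":
            g = focal_density(stack, layer, radius_km)
        else:
            raise LayerError(f"unknown summary {summary!r} for variable {var!r}")
        grids[var] = g
    return grids


def extract_table(
    stack: EnvStack,
    occurrences: pd.DataFrame,
    spec: dict[str, tuple[str, str, float]],
) -> VariableTable:
    """Sample each variable grid at the occurrence cells.

    Rows falling on nodata in any variable are dropped (count logged and
    recorded on the returned table); occurrences outside the grid raise.
    """
    rows = occurrences["row"].to_numpy(dtype=int)
    cols = occurrences["col"].to_numpy(dtype=int)
    nr, nc = stack.shape
    bad = (rows < 0) | (rows >= nr) | (cols < 0) | (cols >= nc)
    if bad.any():
        raise LayerError(f"occurrences outside grid at rows {np.nonzero(bad)[0].tolist()}")
    grids = build_variable_grids(stack, spec)
    data = {var: g[rows, cols] for var, g in grids.items()}
    df = pd.DataFrame(data, index=occurrences.index)
    keep = ~df.isna().any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("extract_table: dropped %d occurrence rows on nodata", n_dropped)
    return VariableTable(data=df.loc[keep], provenance=dict(spec), n_dropped=n_dropped)
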