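"""Synthetic landscapes with a planted ecological-minimum niche.

Generates spatially autocorrelated environmental rasters in which a known
low-variance subspace (the planted "minimum" directions) holds inside a
suitable region around population centers, plus occurrence points (leks)
clustered into populations and degraded historic locations.  Every
downstream stage — variable extraction, partitioned-D2 fitting, evaluation
and connectivity — is testable against the planted truth.

The construction: p independent white-noise fields are smoothed with a
Gaussian kernel (scale ``corr_length`` cells) and rescaled to unit variance,
giving a vector field f(cell) with ~N(0, I) marginals.  An orthonormal basis
Q = [B_min | B_perp] completes the m planted minimum directions.  Cell
environments are

    x = mu + Q diag(s) Q^T f,

with s = sigma_min along the minimum directions inside the suitable region
and s = sigma_free elsewhere and along the free directions.  Inside the
suitable region the projection of (x - mu) onto each minimum direction
therefore has SD sigma_min; outside it has SD sigma_free, so random
background cells violate the minimums and score near-zero HSI.

The true niche-membership statistic of a cell is the squared norm of the
minimum-direction projections, q(x) = ||B_min^T (x - mu)||^2.  Leks are
sampled from the best ``presence_quantile`` of q near population centers;
historic locations from the worst decile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .layers import EnvStack


class SyntheticError(ValueError):
    """Invalid generator configuration or infeasible request."""


@dataclass
class LandscapeConfig:
    """Grid geometry and field parameters for a synthetic landscape."""

    n_rows: int = 64
    n_cols: int = 64
    cell_km: float = 1.0
    p: int = 10
    corr_length: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 16 or self.n_cols < 16:
            raise SyntheticError("grid must be at least 16x16")
        if self.p < 3:
            raise SyntheticError("need at least 3 environmental variables")
        if self.cell_km <= 0:
            raise SyntheticError("cell_km must be positive")
        if self.corr_length < 0:
            raise SyntheticError("corr_length must be >= 0")


@dataclass
class PlantedNiche:
    """Known niche: mean vector, minimum directions and their spreads.

    ``B_min`` columns are the orthonormal minimum directions (m < p);
    ``sigma_min`` the (small) SDs along them inside suitable habitat;
    ``sigma_free`` the SD along the orthogonal complement (and along every
    direction outside suitable habitat).  ``presence_quantile`` is the
    fraction of best-scoring cells eligible to hold an occurrence.
    """

    mu: np.ndarray
    B_min: np.ndarray
    sigma_min: np.ndarray
    sigma_free: float = 1.0
    presence_quantile: float = 0.25

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.B_min = np.asarray(self.B_min, dtype=float)
        self.sigma_min = np.atleast_1d(np.asarray(self.sigma_min, dtype=float))
        p, m = self.B_min.shape
        if m >= p or self.mu.shape != (p,):
            raise SyntheticError("B_min must be p x m with m < p and mu length p")
        if self.sigma_min.shape == (1,):
            self.sigma_min = np.repeat(self.sigma_min, m)
        if self.sigma_min.shape != (m,):
            raise SyntheticError("sigma_min must have one entry per minimum direction")
        G = self.B_min.T @ self.B_min
        if not np.allclose(G, np.eye(m), atol=1e-8):
            raise SyntheticError("columns of B_min must be orthonormal")
        if np.any(self.sigma_min >= self.sigma_free):
            raise SyntheticError("every sigma_min must be < sigma_free")
        if not 0 < self.presence_quantile <= 1:
            raise SyntheticError("presence_quantile must be in (0, 1]")

    @property
    def p(self) -> int:
        return self.B_min.shape[0]

    @property
    def m(self) -> int:
        return self.B_min.shape[1]


def random_niche(p: int, m: int, seed: int, sigma_min: float = 0.1,
                 sigma_free: float = 1.0,
                 presence_quantile: float = 0.25) -> PlantedNiche:
    """A generic planted niche: random mean, random orthonormal B_min."""
    rng = np.random.default_rng(seed)
    mu = rng.normal(0.0, 1.0, size=p)
    A = rng.normal(size=(p, m))
    q, _ = np.linalg.qr(A)
    return PlantedNiche(mu=mu, B_min=q[:, :m], sigma_min=np.full(m, sigma_min),
                        sigma_free=sigma_free, presence_quantile=presence_quantile)


@dataclass
class PopulationLayout:
    """Population centers, dispersion and lek counts."""

    centers: list[tuple[int, int]]
    leks_per_pop: list[int]
    spread_cells: float = 6.0
    suitable_radius_cells: float = 14.0
    count_lognormal_params: tuple[float, float] = (2.5, 1.0)

    def __post_init__(self) -> None:
        if not self.centers:
            raise SyntheticError("need at least one population")
        if len(self.leks_per_pop) != len(self.centers):
            raise SyntheticError("leks_per_pop must match centers")
        if any(n < 1 for n in self.leks_per_pop):
            raise SyntheticError("each population needs at least one lek")

    @property
    def n_pops(self) -> int:
        return len(self.centers)


def default_layout(config: LandscapeConfig, n_pops: int = 4,
                   leks_per_pop: int | list[int] = 125,
                   seed: int | None = None) -> PopulationLayout:
    """Population centers spread over the interior of the grid."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    r0, c0 = config.n_rows / 2.0, config.n_cols / 2.0
    ang = rng.uniform(0, 2 * np.pi)
    centers = []
    for i in range(n_pops):
        a = ang + 2 * np.pi * i / n_pops
        rad = 0.22 * min(config.n_rows, config.n_cols)
        centers.append((int(r0 + rad * np.sin(a)), int(c0 + rad * np.cos(a))))
    if isinstance(leks_per_pop, int):
        per = [leks_per_pop // n_pops] * n_pops
        for i in range(leks_per_pop - sum(per)):
            per[i] += 1
    else:
        per = list(leks_per_pop)
    return PopulationLayout(centers=centers, leks_per_pop=per)


# ---------------------------------------------------------------------------
# raster generation
# ---------------------------------------------------------------------------

def _study_mask(n_rows: int, n_cols: int) -> np.ndarray:
    """True inside the elliptical study area inscribed in the grid."""
    r = (np.arange(n_rows)[:, None] + 0.5 - n_rows / 2) / (n_rows / 2)
    c = (np.arange(n_cols)[None, :] + 0.5 - n_cols / 2) / (n_cols / 2)
    return r ** 2 + c ** 2 <= 1.0


def _suitable_mask(config: LandscapeConfig, layout: PopulationLayout | None,
                   study: np.ndarray) -> np.ndarray:
    """Union of discs around population centers, clipped to the study area."""
    rr = np.arange(config.n_rows)[:, None]
    cc = np.arange(config.n_cols)[None, :]
    if layout is None:
        radius = 0.30 * min(config.n_rows, config.n_cols)
        centers = [(config.n_rows // 2, config.n_cols // 2)]
    else:
        radius = layout.suitable_radius_cells
        centers = layout.centers
    m = np.zeros((config.n_rows, config.n_cols), dtype=bool)
    for r0, c0 in centers:
        if not (0 <= r0 < config.n_rows and 0 <= c0 < config.n_cols):
            raise SyntheticError(f"population center {(r0, c0)} outside grid")
        m |= (rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2
    return m & study


def _smooth_unit_fields(config: LandscapeConfig, rng: np.random.Generator) -> np.ndarray:
    """p stacked fields, Gaussian-smoothed and rescaled to unit variance."""
    fields = rng.standard_normal((config.p, config.n_rows, config.n_cols))
    if config.corr_length > 0:
        fields = ndimage.gaussian_filter(
            fields, sigma=(0.0, config.corr_length, config.corr_length))
    sd = fields.std(axis=(1, 2), keepdims=True)
    sd[sd == 0] = 1.0
    return fields / sd


def gen_env_stack(config: LandscapeConfig, niche: PlantedNiche,
                  layout: PopulationLayout | None = None) -> EnvStack:
    """Environmental raster stack with the niche planted in suitable habitat.

    Layers are named ``env_00`` ... and marked ``continuous``; cells outside
    the elliptical study area carry NaN and are flagged in the nodata mask.
    The EnvStack gains two bookkeeping attributes used by the occurrence
    generators: ``true_q`` (the planted niche-membership statistic per cell)
    and ``suitable_mask``.
    """
    if niche.p != config.p:
        raise SyntheticError(f"niche has p={niche.p} but config p={config.p}")
    rng = np.random.default_rng(config.seed)
    study = _study_mask(config.n_rows, config.n_cols)
    suitable = _suitable_mask(config, layout, study)

    f = _smooth_unit_fields(config, rng)                      # (p, R, C)
    # complete B_min to an orthonormal basis Q = [B_min | B_perp]
    p, m = niche.p, niche.m
    q_full, _ = np.linalg.qr(np.hstack([niche.B_min, np.eye(p)]))
    Q = np.hstack([niche.B_min, q_full[:, m:p]])
    s_in = np.concatenate([niche.sigma_min, np.full(p - m, niche.sigma_free)])
    s_out = np.full(p, niche.sigma_free)

    fv = f.reshape(p, -1)                                     # (p, n_cells)
    proj = Q.T @ fv                                           # basis coords
    scale = np.where(suitable.reshape(1, -1), s_in[:, None], s_out[:, None])
    x = niche.mu[:, None] + Q @ (scale * proj)                # (p, n_cells)

    layers: dict[str, np.ndarray] = {}
    for i in range(p):
        g = x[i].reshape(config.n_rows, config.n_cols).copy()
        g[~study] = np.nan
        layers[f"env_{i:02d}"] = g

    stack = EnvStack(layers=layers, nodata_mask=~study, cell_km=config.cell_km,
                     layer_kinds={n: "continuous" for n in layers})
    dev = x - niche.mu[:, None]
    qstat = ((niche.B_min.T @ dev) ** 2).sum(axis=0)
    qgrid = qstat.reshape(config.n_rows, config.n_cols).copy()
    qgrid[~study] = np.nan
    stack.true_q = qgrid
    stack.suitable_mask = suitable
    return stack


def true_niche_statistic(stack: EnvStack, niche: PlantedNiche) -> np.ndarray:
    """||B_min^T (x - mu)||^2 per cell, recomputed from the stored layers."""
    x = np.stack([stack.layers[n] for n in stack.names])      # (p, R, C)
    dev = x - niche.mu[:, None, None]
    q = np.einsum("pm,prc->mrc", niche.B_min, dev)
    out = (q ** 2).sum(axis=0)
    out[stack.nodata_mask] = np.nan
    return out


# ---------------------------------------------------------------------------
# occurrence generation
# ---------------------------------------------------------------------------

OCCURRENCE_COLUMNS = ["x_km", "y_km", "row", "col", "population", "count", "status"]


def _cells_to_frame(rows: np.ndarray, cols: np.ndarray, pops: list, counts: np.ndarray,
                    status: str, cell_km: float) -> pd.DataFrame:
    return pd.DataFrame({
        "x_km": (cols + 0.5) * cell_km,
        "y_km": (rows + 0.5) * cell_km,
        "row": rows.astype(int),
        "col": cols.astype(int),
        "population": pops,
        "count": counts,
        "status": status,
    }, columns=OCCURRENCE_COLUMNS)


def gen_occurrences(stack: EnvStack, niche: PlantedNiche, layout: PopulationLayout,
                    seed: int) -> pd.DataFrame:
    """Lek occurrences sampled from the best niche cells near each center.

    Eligible cells are the best ``presence_quantile`` of the true statistic
    over the study area; within a population they are drawn without
    replacement with Gaussian weight exp(-d^2 / 2 spread^2) toward the
    center.  Each record gets a population id, a lognormal male count
    (ceiled to >= 1) and status ``active``; cells are unique across the
    whole table.
    """
    rng = np.random.default_rng(seed)
    q = true_niche_statistic(stack, niche)
    valid = ~stack.nodata_mask & np.isfinite(q)
    cutoff = np.quantile(q[valid], niche.presence_quantile)
    eligible = valid & (q <= cutoff)

    taken = np.zeros(stack.shape, dtype=bool)
    rows_all, cols_all, pops_all = [], [], []
    for pid, ((r0, c0), n_leks) in enumerate(zip(layout.centers, layout.leks_per_pop)):
        avail = eligible & ~taken
        rr, cc = np.nonzero(avail)
        if rr.size < n_leks:
            raise SyntheticError(
                f"population {pid}: requested {n_leks} leks but only "
                f"{rr.size} eligible cells remain")
        d2 = (rr - r0) ** 2.0 + (cc - c0) ** 2.0
        w = np.exp(-0.5 * d2 / max(layout.spread_cells, 1e-6) ** 2)
        if w.sum() <= 0:
            w = np.ones_like(w)
        idx = rng.choice(rr.size, size=n_leks, replace=False, p=w / w.sum())
        taken[rr[idx], cc[idx]] = True
        rows_all.append(rr[idx])
        cols_all.append(cc[idx])
        pops_all.extend([pid] * n_leks)

    rows = np.concatenate(rows_all)
    cols = np.concatenate(cols_all)
    meanlog, sdlog = layout.count_lognormal_params
    counts = np.ceil(rng.lognormal(meanlog, sdlog, size=rows.size)).astype(int)
    counts = np.maximum(counts, 1)
    return _cells_to_frame(rows, cols, pops_all, counts, "active", stack.cell_km)


def gen_historic(stack: EnvStack, niche: PlantedNiche, n: int,
                 seed: int) -> pd.DataFrame:
    """Historic (extirpated) locations from the worst decile of niche cells."""
    if n < 1:
        raise SyntheticError("n must be >= 1")
    rng = np.random.default_rng(seed)
    q = true_niche_statistic(stack, niche)
    valid = ~stack.nodata_mask & np.isfinite(q)
    cutoff = np.quantile(q[valid], 0.9)
    worst = valid & (q >= cutoff)
    rr, cc = np.nonzero(worst)
    if rr.size < n:
        raise SyntheticError(f"requested {n} historic cells but only {rr.size} available")
    idx = rng.choice(rr.size, size=n, replace=False)
    counts = np.zeros(n, dtype=int)
    return _cells_to_frame(rr[idx], cc[idx], [-1] * n, counts, "historic",
                           stack.cell_km)
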