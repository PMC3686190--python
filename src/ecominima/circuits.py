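"""Circuit-theory landscape connectivity from an HSI-derived resistance map.

The landscape is treated as an electrical network: every in-mask cell is a
node, neighboring cells are joined by a resistor whose value is the mean of
the two cell resistances times the center-to-center distance (1 for
orthogonal, sqrt(2) for diagonal neighbors, in cell units).  Cell resistance
is the reciprocal of the habitat similarity index, floored and clamped to
[1, 100000]; cells outside the species' historic range get the ceiling
value so map edges carry negligible current.

Connectivity is solved in all-to-one mode: each lek cell in turn injects a
current equal to its mean annual male count while every other lek cell is
held at ground (0 V).  Per solve, the node current is the half-sum of
absolute incident branch currents (the injected amplitude at the source);
summing node currents over all solves yields the cumulative current map, a
proxy for movement potential.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import csgraph
from scipy.sparse.linalg import splu

logger = logging.getLogger("ecominima")

R_MIN = 1.0
R_MAX = 100_000.0
HSI_FLOOR = 1e-5
RESIDUAL_TOL = 1e-10


class CircuitError(ValueError):
    pass


# ---------------------------------------------------------------------------
# resistance surface
# ---------------------------------------------------------------------------

def resistance_from_hsi(hsi_grid: np.ndarray, range_mask: np.ndarray | None = None,
                        r_min: float = R_MIN, r_max: float = R_MAX,
                        hsi_floor: float = HSI_FLOOR,
                        rule: str = "reciprocal") -> np.ndarray:
    """Resistance raster: inverse HSI scaled from r_min (HSI=1) to r_max.

    ``reciprocal`` (default): r = 1 / max(HSI, floor), clamped to
    [r_min, r_max]; ``linear``: 1/HSI rescaled linearly onto [r_min, r_max].
    Cells outside ``range_mask`` (the species' historic range) are set to
    exactly r_max; NaN cells stay NaN.
    """
    h = np.asarray(hsi_grid, dtype=float)
    finite = np.isfinite(h)
    if np.any((h[finite] < 0) | (h[finite] > 1)):
        raise CircuitError("HSI values must lie in [0, 1]")
    inv = 1.0 / np.maximum(h, hsi_floor)
    if rule == "reciprocal":
        # at or below the floor the reciprocal saturates: pin exactly at r_max
        r = np.where(h <= hsi_floor, r_max, np.clip(inv, r_min, r_max))
    elif rule == "linear":
        inv_min, inv_max = 1.0, 1.0 / hsi_floor
        r = r_min + (inv - inv_min) * (r_max - r_min) / (inv_max - inv_min)
        r = np.clip(r, r_min, r_max)
    else:
        raise CircuitError(f"unknown resistance rule {rule!r}")
    out = np.where(finite, r, np.nan)
    if range_mask is not None:
        out[finite & ~range_mask] = r_max
    return out


# ---------------------------------------------------------------------------
# conductance graph
# ---------------------------------------------------------------------------

@dataclass
class CircuitGraph:
    """Sparse conductance graph over in-mask raster cells."""

    node_of_cell: np.ndarray        # (R, C) int grid, -1 where masked
    cells: np.ndarray               # (n, 2) row/col per node
    edges: np.ndarray               # (m, 2) node pairs i < j
    conductance: np.ndarray         # (m,)
    neighborhood: int = 8

    @property
    def n_nodes(self) -> int:
        return self.cells.shape[0]

    def laplacian(self) -> sparse.csc_matrix:
        i, j = self.edges[:, 0], self.edges[:, 1]
        g = self.conductance
        n = self.n_nodes
        A = sparse.coo_matrix((np.concatenate([g, g]),
                               (np.concatenate([i, j]), np.concatenate([j, i]))),
                              shape=(n, n)).tocsr()
        deg = np.asarray(A.sum(axis=1)).ravel()
        return (sparse.diags(deg) - A).tocsc()

    def components(self) -> np.ndarray:
        i, j = self.edges[:, 0], self.edges[:, 1]
        A = sparse.coo_matrix((self.conductance, (i, j)),
                              shape=(self.n_nodes, self.n_nodes))
        _, labels = csgraph.connected_components(A, directed=False)
        return labels


_OFFSETS_4 = [(0, 1, 1.0), (1, 0, 1.0)]
_OFFSETS_8 = _OFFSETS_4 + [(1, 1, np.sqrt(2.0)), (1, -1, np.sqrt(2.0))]


def build_graph(resistance: np.ndarray, neighborhood: int = 8) -> CircuitGraph:
    """Conductance graph: g_ij = 1 / (d_ij * (r_i + r_j) / 2).

    ``d_ij`` is 1 for orthogonal and sqrt(2) for diagonal neighbors (cell
    units); NaN (nodata) cells are excluded.
    """
    if neighborhood not in (4, 8):
        raise CircuitError("neighborhood must be 4 or 8")
    r = np.asarray(resistance, dtype=float)
    valid = np.isfinite(r)
    n = int(valid.sum())
    if n < 2:
        raise CircuitError("need at least 2 in-mask cells")
    node = np.full(r.shape, -1, dtype=int)
    node[valid] = np.arange(n)
    cells = np.argwhere(valid)

    offsets = _OFFSETS_4 if neighborhood == 4 else _OFFSETS_8
    ei, ej, g = [], [], []
    nr, nc = r.shape
    for dr, dc, dist in offsets:
        r0s = slice(max(0, -dr), nr - max(0, dr))
        c0s = slice(max(0, -dc), nc - max(0, dc))
        r1s = slice(max(0, dr), nr + min(0, dr))
        c1s = slice(max(0, dc), nc + min(0, dc))
        a, b = node[r0s, c0s], node[r1s, c1s]
        ok = (a >= 0) & (b >= 0)
        ra, rb = r[r0s, c0s][ok], r[r1s, c1s][ok]
        ei.append(a[ok])
        ej.append(b[ok])
        g.append(1.0 / (dist * (ra + rb) / 2.0))
    i = np.concatenate(ei)
    j = np.concatenate(ej)
    lo, hi = np.minimum(i, j), np.maximum(i, j)
    edges = np.stack([lo, hi], axis=1)
    return CircuitGraph(node_of_cell=node, cells=cells, edges=edges,
                        conductance=np.concatenate(g), neighborhood=neighborhood)


# ---------------------------------------------------------------------------
# solves
# ---------------------------------------------------------------------------

def _solve_grounded(L: sparse.csc_matrix, ground: np.ndarray,
                    injection: np.ndarray,
                    component: np.ndarray | None = None) -> np.ndarray:
    """Node voltages with ``ground`` nodes fixed at 0 V.

    Solves the reduced Laplacian system (restricted to ``component`` nodes
    when given, so disconnected islands do not make it singular); raises if
    the relative residual exceeds RESIDUAL_TOL.
    """
    n = L.shape[0]
    pool = np.arange(n) if component is None else np.asarray(component)
    free = np.setdiff1d(pool, ground, assume_unique=False)
    Lff = L[np.ix_(free, free)].tocsc()
    b = injection[free]
    try:
        v_free = splu(Lff).solve(b)
    except RuntimeError as exc:  # singular factorization
        raise CircuitError(f"singular circuit system: {exc}") from exc
    resid = np.linalg.norm(Lff @ v_free - b)
    scale = np.linalg.norm(b)
    if scale > 0 and resid / scale > RESIDUAL_TOL:
        raise CircuitError(f"solver residual {resid / scale:.2e} above tolerance")
    v = np.zeros(n)
    v[free] = v_free
    return v


def _node_currents(graph: CircuitGraph, v: np.ndarray) -> np.ndarray:
    """Half-sum of absolute incident branch currents per node."""
    i, j = graph.edges[:, 0], graph.edges[:, 1]
    branch = np.abs(graph.conductance * (v[i] - v[j]))
    out = np.zeros(graph.n_nodes)
    np.add.at(out, i, branch)
    np.add.at(out, j, branch)
    return 0.5 * out


def _absorbed_at(graph: CircuitGraph, v: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """Signed current flowing into each listed node (positive = absorbed)."""
    i, j = graph.edges[:, 0], graph.edges[:, 1]
    flow = graph.conductance * (v[i] - v[j])  # positive i -> j
    inflow = np.zeros(graph.n_nodes)
    np.add.at(inflow, j, flow)
    np.add.at(inflow, i, -flow)
    return inflow[nodes]


@dataclass
class CurrentMap:
    """Cumulative node current plus per-source provenance."""

    cumulative: np.ndarray          # grid, NaN on nodata
    per_source: pd.DataFrame        # source id, row, col, amplitude, absorbed
    skipped: list[int] = field(default_factory=list)


def solve_all_to_one(graph: CircuitGraph, source_cells: np.ndarray,
                     amplitudes: np.ndarray) -> CurrentMap:
    """Iterative all-to-one circuit solves, summed into a cumulative map.

    For each source in turn: every other source cell is grounded at 0 V and
    the source injects its amplitude; node currents (half-sum of absolute
    incident branch currents, amplitude at the source itself) accumulate
    across iterations.  Sources in a component containing no other source
    are skipped with a warning.
    """
    source_cells = np.asarray(source_cells, dtype=int)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if source_cells.shape[0] < 2:
        raise CircuitError("need at least 2 source cells")
    if np.any(amplitudes <= 0):
        raise CircuitError("source amplitudes must be positive")
    nodes = graph.node_of_cell[source_cells[:, 0], source_cells[:, 1]]
    if np.any(nodes < 0):
        raise CircuitError("source cell outside the graph mask")
    if np.unique(nodes).size != nodes.size:
        raise CircuitError("duplicate source cells")

    labels = graph.components()
    L = graph.laplacian()
    cum = np.zeros(graph.n_nodes)
    rows, skipped = [], []
    for s in range(nodes.size):
        others = np.delete(nodes, s)
        reachable = others[labels[others] == labels[nodes[s]]]
        if reachable.size == 0:
            logger.warning("source %d isolated from all other sources; skipped", s)
            skipped.append(s)
            continue
        inj = np.zeros(graph.n_nodes)
        inj[nodes[s]] = amplitudes[s]
        comp = np.nonzero(labels == labels[nodes[s]])[0]
        v = _solve_grounded(L, others, inj, component=comp)
        nc = _node_currents(graph, v)
        nc[nodes[s]] = amplitudes[s]
        absorbed = _absorbed_at(graph, v, others).sum()
        cum += nc
        rows.append({"source": s, "row": int(source_cells[s, 0]),
                     "col": int(source_cells[s, 1]),
                     "amplitude": float(amplitudes[s]),
                     "absorbed": float(absorbed)})
    grid = np.full(graph.node_of_cell.shape, np.nan)
    grid[graph.node_of_cell >= 0] = cum[graph.node_of_cell[graph.node_of_cell >= 0]]
    return CurrentMap(cumulative=grid, per_source=pd.DataFrame(rows),
                      skipped=skipped)


def effective_resistance(graph: CircuitGraph, a: int, b: int) -> float:
    """Two-terminal effective resistance: voltage at ``a`` under unit
    injection with ``b`` grounded."""
    if a == b:
        raise CircuitError("terminals must differ")
    labels = graph.components()
    if labels[a] != labels[b]:
        raise CircuitError("terminals are disconnected")
    inj = np.zeros(graph.n_nodes)
    inj[a] = 1.0
    comp = np.nonzero(labels == labels[a])[0]
    v = _solve_grounded(graph.laplacian(), np.array([b]), inj, component=comp)
    return float(v[a])
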