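"""Partitioned Mahalanobis D2 niche model and habitat similarity index.

The Mahalanobis distance of an environmental vector x from the multivariate
occurrence mean mu, computed on the correlation scale, decomposes along the
principal components of the occurrence correlation matrix R:

    z = (x - mu) / sigma
    D2 = z^T R^{-1} z = sum_j (e_j . z)^2 / lambda_j

Each term is one *partition*.  Partitions are orthogonal and additive: the
full sum recovers D2 exactly.  Small-eigenvalue partitions (lambda <= 1)
capture combinations of variables that are nearly constant wherever the
species occurs — the *ecological minimums*.  The reduced-rank statistic

    D2(k) = sum_{j = k..p} (e_j . z)^2 / lambda_j          (tail-sum)

measures departure from those minimums only, ignoring the high-variance
components the species tolerates.  A habitat similarity index rescales it
to [0, 1] via the chi-square upper tail with df = p - k + 1 (the number of
summed partitions), so HSI = 1 exactly at the occurrence mean and decays
monotonically with D2(k).

Fitting supports a single PCA of the occurrence correlation matrix
(``fit_single``) and a bootstrap-averaged fit (``bootstrap_fit``): many
population-capped resamples, each decomposed, components matched across
iterations by eigenvalue rank, eigenvector signs aligned to a running
reference before averaging, and averaged eigenvectors renormalized.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .layers import EnvStack, VariableTable, build_variable_grids

logger = logging.getLogger("ecominima")

EIGVAL_FLOOR = 1e-10


class ModelError(ValueError):
    """Degenerate data or invalid model parameters."""


@dataclass
class PartitionModel:
    """Fitted partitioned-D2 model.

    Attributes
    ----------
    mu, sigma
        Occurrence means and SDs used for standardization.
    eigvals, eigvecs
        Descending eigenvalues and unit eigenvectors (columns) of the
        occurrence correlation matrix; for a bootstrap-averaged model these
        are averages over iterations.
    k_selected
        Boundary partition: D2(k) sums partitions k..p.
    mode
        ``tail-sum`` (default) or ``single-partition`` (partition k alone).
    """

    mu: np.ndarray
    sigma: np.ndarray
    eigvals: np.ndarray
    eigvecs: np.ndarray
    var_names: list[str]
    k_selected: int = 1
    mode: str = "tail-sum"
    n_boot: int = 1
    pop_cap: int | None = None
    seed: int | None = None
    orthogonality_dev: float = 0.0
    averaged: bool = False

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.eigvals = np.asarray(self.eigvals, dtype=float)
        self.eigvecs = np.asarray(self.eigvecs, dtype=float)
        if np.any(self.sigma <= 0):
            raise ModelError("all standardization SDs must be positive")
        if not 1 <= self.k_selected <= self.p:
            raise ModelError(f"k_selected={self.k_selected} outside 1..{self.p}")
        if self.mode not in ("tail-sum", "single-partition"):
            raise ModelError(f"unknown D2(k) mode {self.mode!r}")

    @property
    def p(self) -> int:
        return self.mu.size

    @property
    def df(self) -> int:
        """Chi-square degrees of freedom used by the HSI rescaling."""
        if self.mode == "single-partition":
            return 1
        return self.p - self.k_selected + 1

    def with_k(self, k: int) -> "PartitionModel":
        """Same model with a different boundary partition."""
        out = PartitionModel(mu=self.mu, sigma=self.sigma, eigvals=self.eigvals,
                             eigvecs=self.eigvecs, var_names=self.var_names,
                             k_selected=k, mode=self.mode, n_boot=self.n_boot,
                             pop_cap=self.pop_cap, seed=self.seed,
                             orthogonality_dev=self.orthogonality_dev,
                             averaged=self.averaged)
        return out

    # -- serialization -----------------------------------------------------
    def to_json(self, path) -> None:
        obj = {
            "var_names": self.var_names,
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "eigvals": self.eigvals.tolist(),
            "eigvecs": self.eigvecs.tolist(),
            "k_selected": self.k_selected,
            "df": self.df,
            "mode": self.mode,
            "n_boot": self.n_boot,
            "pop_cap": self.pop_cap,
            "seed": self.seed,
            "orthogonality_dev": self.orthogonality_dev,
            "averaged": self.averaged,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PartitionModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(mu=np.array(obj["mu"]), sigma=np.array(obj["sigma"]),
                   eigvals=np.array(obj["eigvals"]), eigvecs=np.array(obj["eigvecs"]),
                   var_names=list(obj["var_names"]), k_selected=obj["k_selected"],
                   mode=obj["mode"], n_boot=obj["n_boot"], pop_cap=obj["pop_cap"],
                   seed=obj["seed"], orthogonality_dev=obj["orthogonality_dev"],
                   averaged=obj["averaged"])


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _check_table(X: np.ndarray, names: list[str]) -> None:
    n, p = X.shape
    if n <= p:
        raise ModelError(f"need n > p occurrences (got n={n}, p={p})")
    sd = X.std(axis=0, ddof=1)
    const = np.nonzero(sd == 0)[0]
    if const.size:
        raise ModelError(f"constant variable(s): {[names[i] for i in const]}")


def fit_single(table: VariableTable) -> PartitionModel:
    """PCA of the occurrence correlation matrix; deterministic up to sign.

    Eigenvalues are returned descending; their sum equals p (the trace of a
    correlation matrix).
    """
    X = table.values
    names = table.columns
    _check_table(X, names)
    mu = X.mean(axis=0)
    sigma = X.std(axis=0, ddof=1)
    R = np.corrcoef(X, rowvar=False)
    vals, vecs = np.linalg.eigh(R)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    # canonical sign: largest-magnitude coefficient positive
    for j in range(vecs.shape[1]):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return PartitionModel(mu=mu, sigma=sigma, eigvals=vals, eigvecs=vecs,
                          var_names=names)


def _capped_sample(groups: dict, pop_cap: int, rng: np.random.Generator) -> np.ndarray:
    idx = []
    for pid, members in groups.items():
        take = min(len(members), pop_cap)
        idx.append(rng.choice(members, size=take, replace=False))
    return np.concatenate(idx)


def bootstrap_fit(table: VariableTable, populations: np.ndarray,
                  n_boot: int = 1000, pop_cap: int = 25, seed: int = 0,
                  replace: bool = False) -> PartitionModel:
    """Bootstrap-averaged PCA with per-population capping and sign alignment.

    Each iteration draws at most ``pop_cap`` occurrences per population
    (without replacement by default), fits a single PCA, matches components
    to the running model by eigenvalue rank, flips any eigenvector whose dot
    product with the running mean reference is negative, and accumulates.
    The final model averages mu, sigma, eigenvalues and eigenvectors
    element-wise, renormalizes the averaged eigenvectors to unit length and
    records the residual non-orthogonality max |e_i . e_j| (i != j).
    """
    populations = np.asarray(populations)
    if populations.shape[0] != table.data.shape[0]:
        raise ModelError("populations must align with table rows")
    rng = np.random.default_rng(seed)
    groups = {pid: np.nonzero(populations == pid)[0]
              for pid in pd.unique(populations)}

    sum_mu = sum_sigma = sum_vals = sum_vecs = None
    ref_vecs = None
    for it in range(n_boot):
        idx = _capped_sample(groups, pop_cap, rng)
        if replace:
            idx = rng.choice(idx, size=idx.size, replace=True)
        m = fit_single(VariableTable(data=table.data.iloc[idx],
                                     provenance=table.provenance))
        vecs = m.eigvecs.copy()
        if ref_vecs is None:
            ref_vecs = vecs.copy()
        else:
            flips = np.sign(np.einsum("ij,ij->j", vecs, ref_vecs))
            flips[flips == 0] = 1.0
            vecs *= flips
            # running mean reference keeps later iterations aligned
            ref_vecs = ref_vecs + (vecs - ref_vecs) / (it + 1)
        if sum_mu is None:
            sum_mu = m.mu.copy()
            sum_sigma = m.sigma.copy()
            sum_vals = m.eigvals.copy()
            sum_vecs = vecs
        else:
            sum_mu += m.mu
            sum_sigma += m.sigma
            sum_vals += m.eigvals
            sum_vecs += vecs

    mu = sum_mu / n_boot
    sigma = sum_sigma / n_boot
    vals = sum_vals / n_boot
    vecs = sum_vecs / n_boot
    norms = np.linalg.norm(vecs, axis=0)
    if np.any(norms == 0):
        raise ModelError("averaged eigenvector collapsed to zero")
    vecs = vecs / norms
    G = vecs.T @ vecs
    dev = float(np.max(np.abs(G - np.diag(np.diag(G)))))
    logger.info("bootstrap_fit: %d iterations, orthogonality deviation %.3e",
                n_boot, dev)
    return PartitionModel(mu=mu, sigma=sigma, eigvals=vals, eigvecs=vecs,
                          var_names=table.columns, n_boot=n_boot, pop_cap=pop_cap,
                          seed=seed, orthogonality_dev=dev, averaged=n_boot > 1)


def select_k(model: PartitionModel, threshold: float = 1.0) -> int:
    """Smallest k whose eigenvalue is <= threshold (default 1.0).

    Partitions with eigenvalues at or below 1 explain little variance and
    represent the invariant — limiting — environmental relationships.
    """
    below = np.nonzero(model.eigvals <= threshold)[0]
    if below.size == 0:
        return model.p
    return int(below[0]) + 1


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _standardize(X: np.ndarray, model: PartitionModel) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != model.p:
        raise ModelError(f"expected {model.p} variables, got {X.shape[-1]}")
    return (X - model.mu) / model.sigma


def partition_contributions(x: np.ndarray, model: PartitionModel) -> np.ndarray:
    """Per-partition contribution c_j = (e_j . z)^2 / lambda_j.

    On a single (non-averaged) fit the contributions sum exactly to the full
    Mahalanobis D2 on the correlation scale.
    """
    z = _standardize(x, model)
    lam = np.maximum(model.eigvals, EIGVAL_FLOOR)
    if np.any(model.eigvals < EIGVAL_FLOOR):
        warnings.warn("eigenvalue below floor 1e-10; contributions clipped",
                      RuntimeWarning, stacklevel=2)
    proj = z @ model.eigvecs
    return proj ** 2 / lam


def d2_k(x: np.ndarray, model: PartitionModel, k: int | None = None) -> np.ndarray:
    """Reduced-rank D2: tail sum of partitions k..p (or partition k alone)."""
    if k is None:
        k = model.k_selected
    if not 1 <= k <= model.p:
        raise ModelError(f"k={k} outside 1..{model.p}")
    c = partition_contributions(x, model)
    if model.mode == "single-partition":
        return c[..., k - 1]
    return c[..., k - 1:].sum(axis=-1)


def hsi(d2: np.ndarray, model: PartitionModel, k: int | None = None,
        rescale: str = "chi2") -> np.ndarray:
    """Habitat similarity index in [0, 1] from a D2(k) value.

    ``chi2`` (default): upper-tail probability of a chi-square with
    df = number of summed partitions; strictly decreasing in D2 with
    HSI(0) = 1.  ``minmax`` is a linear alternative useful only for mapping
    a finite batch of scores: 1 - d2/max(d2).
    """
    d2 = np.asarray(d2, dtype=float)
    if np.any(d2 < 0):
        raise ModelError("D2 must be non-negative")
    if k is None:
        k = model.k_selected
    if rescale == "chi2":
        df = 1 if model.mode == "single-partition" else model.p - k + 1
        return stats.chi2.sf(d2, df)
    if rescale == "minmax":
        top = d2.max() if d2.size else 1.0
        return 1.0 - d2 / top if top > 0 else np.ones_like(d2)
    raise ModelError(f"unknown rescale {rescale!r}")


def score_hsi(X: np.ndarray, model: PartitionModel, k: int | None = None) -> np.ndarray:
    """HSI for a batch of raw variable vectors (rows)."""
    return hsi(d2_k(X, model, k), model, k)


def map_hsi(stack: EnvStack, spec: dict[str, tuple[str, str, float]],
            model: PartitionModel, k: int | None = None) -> np.ndarray:
    """Per-cell HSI raster; nodata cells carry NaN.

    ``spec`` maps each model variable to its (layer, summary, radius_km)
    recipe, exactly as used to build the fitting table.
    """
    missing = [v for v in model.var_names if v not in spec]
    if missing:
        raise ModelError(f"extraction spec missing model variable(s): {missing}")
    grids = build_variable_grids(stack, {v: spec[v] for v in model.var_names})
    arr = np.stack([grids[v] for v in model.var_names], axis=-1)  # (R, C, p)
    out = np.full(stack.shape, np.nan)
    ok = ~stack.nodata_mask & np.isfinite(arr).all(axis=-1)
    if ok.any():
        out[ok] = score_hsi(arr[ok], model, k)
    return out


# ---------------------------------------------------------------------------
# partition-selection diagnostics
# ---------------------------------------------------------------------------

@dataclass
class PartitionDiagnostics:
    """Per-k evaluation summary plus the eigenvalue ladder."""

    eigvals: np.ndarray
    delta_eigvals: np.ndarray
    table: pd.DataFrame  # columns: k, eigval, delta, median_cal, median_eval,
    #                               median_historic, auc

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def eigenvalue_ladder_diagnostics(eigvals: np.ndarray) -> pd.DataFrame:
    """Ladder table: k, eigenvalue, adjacent difference lambda_{k-1}-lambda_k."""
    eigvals = np.asarray(eigvals, dtype=float)
    delta = np.concatenate([[np.nan], eigvals[:-1] - eigvals[1:]])
    return pd.DataFrame({"k": np.arange(1, eigvals.size + 1),
                         "eigval": eigvals, "delta": delta})


def diagnostics(model: PartitionModel, cal: np.ndarray, evl: np.ndarray,
                historic: np.ndarray, background: np.ndarray) -> PartitionDiagnostics:
    """Median HSI per point set and presence-background AUC, for every k.

    Inputs are raw variable matrices (rows x p).  AUC compares evaluation
    presences against the background sample.
    """
    from .evaluate import auc as _auc

    for name, arr in (("cal", cal), ("eval", evl), ("historic", historic),
                      ("background", background)):
        if np.asarray(arr).shape[0] == 0:
            raise ModelError(f"empty point set: {name}")
    rows = []
    for k in range(1, model.p + 1):
        s_cal = score_hsi(cal, model, k)
        s_evl = score_hsi(evl, model, k)
        s_his = score_hsi(historic, model, k)
        s_bg = score_hsi(background, model, k)
        rows.append({
            "k": k,
            "eigval": model.eigvals[k - 1],
            "median_cal": float(np.median(s_cal)),
            "median_eval": float(np.median(s_evl)),
            "median_historic": float(np.median(s_his)),
            "auc": float(_auc(s_evl, s_bg)),
        })
    tab = pd.DataFrame(rows)
    ladder = eigenvalue_ladder_diagnostics(model.eigvals)
    tab.insert(2, "delta", ladder["delta"].to_numpy())
    return PartitionDiagnostics(eigvals=model.eigvals.copy(),
                                delta_eigvals=ladder["delta"].to_numpy(),
                                table=tab)
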