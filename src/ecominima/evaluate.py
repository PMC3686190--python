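"""Model evaluation: splits, presence-background ROC, dose-response curves,
HSI thresholds, variable importance and group summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .niche import PartitionModel


class EvalError(ValueError):
    pass


# ---------------------------------------------------------------------------
# calibration / evaluation split
# ---------------------------------------------------------------------------

def split(occurrences: pd.DataFrame, calibration_fraction: float = 0.70,
          seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive, seed-reproducible random split.

    Calibration size is round-half-up(n * fraction); the remainder is the
    evaluation set.
    """
    if not 0 < calibration_fraction < 1:
        raise EvalError("calibration_fraction must be in (0, 1)")
    n = len(occurrences)
    if n < 2:
        raise EvalError("need at least 2 records to split")
    n_cal = int(np.floor(n * calibration_fraction + 0.5))
    n_cal = min(max(n_cal, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    cal = occurrences.iloc[np.sort(perm[:n_cal])]
    evl = occurrences.iloc[np.sort(perm[n_cal:])]
    return cal, evl


def sample_background(nodata_mask: np.ndarray, n: int, seed: int,
                      cell_km: float = 1.0) -> pd.DataFrame:
    """Uniform random in-mask cells (with replacement) as background points."""
    rr, cc = np.nonzero(~nodata_mask)
    if rr.size == 0:
        raise EvalError("mask has no valid cells")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, rr.size, size=n)
    rows, cols = rr[idx], cc[idx]
    return pd.DataFrame({
        "x_km": (cols + 0.5) * cell_km,
        "y_km": (rows + 0.5) * cell_km,
        "row": rows, "col": cols,
        "population": -1, "count": 0, "status": "background",
    })


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

def auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank-based AUC: P(presence outscores background), ties counting 1/2.

    Equivalent to the Mann-Whitney U statistic normalized by n1*n2 and
    invariant under any strictly monotone transform of the scores.
    """
    a = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if a.size == 0 or b.size == 0:
        raise EvalError("auc requires non-empty score sets")
    ranks = stats.rankdata(np.concatenate([a, b]))
    u = ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0
    return float(u / (a.size * b.size))


def median_hsi(scores: np.ndarray) -> float:
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise EvalError("empty score set")
    return float(np.median(scores))


def hsi_threshold(lek_scores: np.ndarray, coverage: float = 0.90) -> float:
    """HSI value exceeded (>=) by at least ``coverage`` of the leks.

    The lower empirical quantile at (1 - coverage), inverse-ECDF (type-1)
    convention: sorted ascending, index ceil(n*q) - 1.
    """
    s = np.sort(np.asarray(lek_scores, dtype=float))
    if s.size == 0:
        raise EvalError("empty score set")
    if not 0 < coverage < 1:
        raise EvalError("coverage must be in (0, 1)")
    q = 1.0 - coverage
    i = max(int(np.ceil(s.size * q)) - 1, 0)
    return float(s[i])


# ---------------------------------------------------------------------------
# dose-response
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseCurve:
    """Mean +- SD of HSI across the study area, and lek proportions, per bin
    of one environmental variable."""

    variable: str
    bin_edges: np.ndarray
    hsi_mean: np.ndarray
    hsi_sd: np.ndarray
    lek_proportion: np.ndarray
    cell_count: np.ndarray
    empty_bins: np.ndarray  # boolean; True where no study-area cell fell in

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_left": self.bin_edges[:-1],
            "bin_right": self.bin_edges[1:],
            "hsi_mean": self.hsi_mean,
            "hsi_sd": self.hsi_sd,
            "lek_proportion": self.lek_proportion,
            "cell_count": self.cell_count,
            "empty": self.empty_bins,
        })


def dose_response(variable_grid: np.ndarray, hsi_grid: np.ndarray,
                  lek_values: np.ndarray, n_bins: int = 20,
                  variable: str = "variable") -> DoseResponseCurve:
    """Bin the study area by one variable; summarize HSI and lek placement.

    Equal-width bins span the in-mask variable range.  Per bin: mean and SD
    of cell HSI, and the proportion of leks whose variable value falls in
    the bin (lek values outside the cell range are clipped into the end
    bins so proportions always sum to 1).
    """
    if n_bins < 2:
        raise EvalError("n_bins must be >= 2")
    v = np.asarray(variable_grid, dtype=float).ravel()
    h = np.asarray(hsi_grid, dtype=float).ravel()
    ok = np.isfinite(v) & np.isfinite(h)
    v, h = v[ok], h[ok]
    if v.size == 0:
        raise EvalError("no valid cells")
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        raise EvalError(f"degenerate range for {variable!r}: all values {lo}")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(v, edges) - 1, 0, n_bins - 1)
    count = np.bincount(idx, minlength=n_bins).astype(float)
    mean = np.full(n_bins, np.nan)
    sd = np.full(n_bins, np.nan)
    sums = np.bincount(idx, weights=h, minlength=n_bins)
    sqs = np.bincount(idx, weights=h * h, minlength=n_bins)
    nz = count > 0
    mean[nz] = sums[nz] / count[nz]
    var = np.maximum(sqs[nz] / count[nz] - mean[nz] ** 2, 0.0)
    sd[nz] = np.sqrt(var)
    lv = np.asarray(lek_values, dtype=float)
    lv = lv[np.isfinite(lv)]
    if lv.size == 0:
        raise EvalError("no finite lek values")
    lidx = np.clip(np.digitize(lv, edges) - 1, 0, n_bins - 1)
    lprop = np.bincount(lidx, minlength=n_bins) / lv.size
    return DoseResponseCurve(variable=variable, bin_edges=edges, hsi_mean=mean,
                             hsi_sd=sd, lek_proportion=lprop, cell_count=count,
                             empty_bins=~nz)


def plot_dose_response(curve: DoseResponseCurve, threshold: float | None = None,
                       ax=None):
    """Dose-response figure: HSI mean +- 1 SD line plus lek-proportion bars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    mid = 0.5 * (curve.bin_edges[:-1] + curve.bin_edges[1:])
    width = np.diff(curve.bin_edges)
    ax2 = ax.twinx()
    ax2.bar(mid, curve.lek_proportion, width=width * 0.9, color="0.7", zorder=1)
    ax2.set_ylabel("proportion of leks")
    ax.plot(mid, curve.hsi_mean, "k-", zorder=3)
    ax.plot(mid, curve.hsi_mean + curve.hsi_sd, "k:", lw=0.8, zorder=3)
    ax.plot(mid, np.clip(curve.hsi_mean - curve.hsi_sd, 0, None), "k:", lw=0.8,
            zorder=3)
    if threshold is not None:
        ax.axhline(threshold, ls="--", color="k", lw=0.8)
    ax.set_xlabel(curve.variable)
    ax.set_ylabel("HSI")
    ax.set_ylim(0, 1)
    ax.set_zorder(ax2.get_zorder() + 1)
    ax.patch.set_visible(False)
    return ax


# ---------------------------------------------------------------------------
# variable importance and group summaries
# ---------------------------------------------------------------------------

def variable_importance(model: PartitionModel, hsi_scores: np.ndarray,
                        table_values: np.ndarray,
                        loading_threshold: float = 0.3,
                        correlation_floor: float = 0.1) -> pd.DataFrame:
    """Per-variable loadings on the boundary partition and HSI correlation.

    Columns: ``loading_k`` = |e_{k,i}| on the boundary component,
    ``loading_tail`` = sqrt(sum_{j>=k} e_{j,i}^2) aggregated over the summed
    tail, ``spearman_hsi`` vs the supplied HSI scores, and an ``important``
    flag (|loading| above threshold AND |correlation| above floor).
    """
    X = np.asarray(table_values, dtype=float)
    s = np.asarray(hsi_scores, dtype=float)
    if X.shape[0] != s.size:
        raise EvalError("hsi_scores must align with table rows")
    k = model.k_selected
    load_k = np.abs(model.eigvecs[:, k - 1])
    load_tail = np.sqrt((model.eigvecs[:, k - 1:] ** 2).sum(axis=1))
    rho = np.full(model.p, np.nan)
    for i in range(model.p):
        if np.std(X[:, i]) > 0 and np.std(s) > 0:
            rho[i] = stats.spearmanr(X[:, i], s).statistic
        else:
            rho[i] = 0.0
    important = (load_k > loading_threshold) & (np.abs(rho) > correlation_floor)
    return pd.DataFrame({
        "variable": model.var_names,
        "loading_k": load_k,
        "loading_tail": load_tail,
        "spearman_hsi": rho,
        "important": important,
    })


def group_summary(groups: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Mean, SE, range and normal 95% CI per variable per group.

    ``groups`` maps a label (e.g. active / historic / study_area) to a
    variable table (DataFrame of raw values).  Output is tidy: one row per
    (group, variable).
    """
    rows = []
    for label, df in groups.items():
        if len(df) == 0:
            raise EvalError(f"empty group {label!r}")
        for var in df.columns:
            v = df[var].to_numpy(dtype=float)
            mean = float(v.mean())
            sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
            se = sd / np.sqrt(v.size)
            rows.append({
                "group": label, "variable": var, "n": v.size,
                "mean": mean, "se": se,
                "min": float(v.min()), "max": float(v.max()),
                "ci_lo": mean - 1.96 * se, "ci_hi": mean + 1.96 * se,
            })
    return pd.DataFrame(rows)
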