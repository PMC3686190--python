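# Methods

## Partitioned Mahalanobis D² and the HSI

The model characterizes a species' environmental niche from presence-only
occurrence records. All variables are standardized by the occurrence means
μ and SDs σ, and the occurrence correlation matrix R is eigendecomposed.
Each eigenpair (λⱼ, eⱼ) defines one *partition* of the Mahalanobis
distance: cⱼ(x) = (eⱼ·z)²/λⱼ with z = (x − μ)/σ. Partitions are orthogonal
and additive — Σⱼcⱼ = zᵀR⁻¹z exactly on a single fit, which the test suite
verifies against a direct matrix inverse to 1e-8.

Small-eigenvalue partitions (λ ≤ 1) are combinations of variables that are
nearly constant wherever the species occurs; they are read as *ecological
minimums* (limiting requirements). Two conventions for the reduced-rank
statistic D²(k) exist in the literature that uses this model family:

* **tail-sum** (our default): D²(k) = Σ_{j=k..p} cⱼ, departure from all
  minimum partitions at once. Precision grows as more partitions are added.
* **single-partition**: cₖ alone. Available via `PartitionModel.mode`.

We default to tail-sum because the count of usable partitions under the
λ ≤ 1 criterion matches the tail reading, and because adding partitions is
the stated way to tighten the model.

**HSI rescaling.** HSI = P(χ²_df > D²(k)) with df = p − k + 1 (the number
of summed partitions; df = 1 in single-partition mode). This maps D² = 0 to
exactly 1, is strictly decreasing, and needs no data-dependent calibration.
A min–max rescale is provided as an alternative for bounded score batches.
If the averaged model's D²(k) were exactly chi-square distributed at
occurrence sites the HSI would be uniform there; in practice the planted
minimums give evaluation leks high scores and background/historic points
scores near 0, which is the contrast the index is used for.

**Boundary partition k.** Default: the smallest k with λₖ ≤ 1.0,
overridable in `RunConfig.k`. In the motivating analyses this choice also
weighed evaluation performance and interpretability; the per-k diagnostics
table (median HSI of calibration/evaluation/historic sets, AUC, eigenvalue
spacing Δλ) is emitted so a user can apply the same judgment.

## Bootstrap averaging

`bootstrap_fit` draws, per iteration, at most `pop_cap` (default 25)
occurrences per population without replacement (with-replacement available
by flag), fits the PCA, matches components across iterations by eigenvalue
rank, and aligns eigenvector signs to a running mean reference (flip when
the dot product is negative) before element-wise averaging — the standard
cure for PCA sign ambiguity. Averaged eigenvectors are renormalized to
unit length but *not* re-orthogonalized; the residual max |eᵢ·eⱼ| is
logged and stored (`orthogonality_dev`, ~6e-2 at the demo scale), and
additivity is only approximate for averaged models. Component matching by
similarity rather than rank would be a refinement; rank matching is used
because the eigenvalue ladder is the object being averaged and reported.
Eigenvalues below 1e-10 are floored in the cⱼ division with a warning.

Defaults n_boot = 1000 and pop_cap = 25 are the study conditions of the
motivating analysis and run in seconds at demo scale.

## Synthetic landscapes

The generator is the testbed: it emulates 10–27 spatially autocorrelated
environmental variables with a *known* low-variance niche subspace.

* **Fields.** Independent white noise per variable, smoothed by a Gaussian
  kernel of scale `corr_length` cells (default 3) and rescaled to unit
  variance. Kernel smoothing was chosen over spectral synthesis for
  simplicity and bit-reproducibility given a seed.
* **Planted niche.** An orthonormal p×m matrix B_min (default m = 2, drawn
  uniformly at random), SD `sigma_min` = 0.1 along those directions inside
  the suitable region versus `sigma_free` = 1.0 elsewhere and along the
  complement. Cell environments are x = μ + Q diag(s) Qᵀ f, so projections
  of (x − μ) onto B_min have SD sigma_min exactly where habitat is
  suitable. The 10:1 variance ratio makes the minimums recoverable from
  ~500 occurrences, mimicking a strongly limiting requirement.
* **Suitable region.** Discs of radius `suitable_radius_cells` around the
  population centers, clipped to an elliptical study-area mask (cells
  outside the ellipse are nodata). This guarantees populations sit in
  plantable habitat.
* **Occurrences.** Leks are unique cells drawn from the best
  `presence_quantile` (default 0.25) of the true statistic
  q = ‖B_minᵀ(x − μ)‖², weighted toward their population center by a
  Gaussian of scale `spread_cells`. Male counts are lognormal(2.5, 1.0)
  ceiled to ≥ 1 — strictly positive and right-skewed like real lek counts.
  Historic (extirpated) locations come from the worst decile of q with
  count 0. Coordinates are 0-based (row, col) with cell centers at
  (row + 0.5, col + 0.5)·cell_km throughout.
* **What it does not emulate:** real sagebrush spatial pattern, fire or
  road geometry (linear features would be per-cell length rasters),
  observation error in lek surveys, or non-Gaussian variable marginals.
  Passing tests therefore demonstrate correctness of the algorithms and
  recoverability of a planted signal — not predictive skill on real data.

Demo study conditions: 64×64 grid, p = 10, m = 2, 4 populations, 500 leks,
99 historic locations, 500 background points, 70/30 calibration split.

## Variable extraction

Circular windows include every cell whose center lies within the radius
(ties included), so a 5-km radius on a 1-km grid is the 81-cell disc.
Windows truncate at the grid edge and at nodata, with means/densities over
the available cells — the common GIS focal-statistics default; the source
analyses do not state their edge rule, so this is our documented choice,
including the truncated-area denominator for densities. Slope/aspect use
the Horn 3×3 stencil with nearest-edge padding; aspect is degrees
clockwise from north and NaN on flat cells. The vector ruggedness measure
sums unit surface normals over an odd square window; flat cells contribute
the vertical normal (0, 0, 1) — the slope→0 limit — rather than being
dropped, which makes all-flat windows well-defined (vrm = 0) and changes
nothing for mixed windows.

## Evaluation

* AUC is the rank-based (Mann–Whitney) presence-vs-background statistic
  with ties counting ½, so auc(a,b) + auc(b,a) = 1 exactly and the value
  is invariant under monotone transforms of scores.
* The HSI coverage threshold is the lower empirical quantile at
  (1 − coverage), inverse-ECDF (type-1) convention, so at least the target
  fraction of leks score at or above it. The convention matters at small n
  and is fixed here for reproducibility.
* Dose-response curves bin the study area into `n_bins` (default 20)
  equal-width bins of one variable, reporting mean ± SD of cell HSI and
  the proportion of leks per bin; lek values outside the cell range clip
  into the end bins so proportions always sum to 1. Bin width is a display
  choice; the sources leave it unstated.
* Variable importance combines the absolute loading on the boundary
  partition (threshold 0.3, configurable), an aggregate tail loading
  √(Σ_{j≥k} e²), and the Spearman correlation with HSI — Spearman because
  the HSI scale is bounded and skewed; the coefficient is not specified by
  the sources.
* Group summaries (active / historic / study area) use normal-approximation
  95% CIs (mean ± 1.96 SE), not bootstrap.

## Connectivity

Resistance r = 1/max(HSI, 1e-5) clamped to [1, 100 000], with cells at or
below the floor pinned exactly at 100 000, and out-of-range cells set to
100 000 so map boundaries carry negligible current. The phrase "scaling
the inverse of the HSI" also admits a linear rescale of 1/HSI; the
parameter-free reciprocal is the default and the linear variant a flag.

The conductance graph uses the 8-neighborhood (4 by flag) with edge
conductance g = 1/(d·(r_i + r_j)/2), d = 1 orthogonal and √2 diagonal in
cell units — the usual raster-circuit construction; the external tools
this emulates do not document their exact formula, so ours is an explicit
contract rather than a reconstruction. Solves are all-to-one: each source
grounded against all other sources, solved by sparse LU on the reduced
Laplacian restricted to the source's connected component (relative
residual ≤ 1e-10 enforced; sources isolated from every other source are
skipped with a warning). The per-cell "current" is the half-sum of
absolute incident branch currents (the injected amplitude at the source
itself, the absorbed current at grounds), summed — not averaged — over
source iterations. Effective resistance, current conservation, voltage
bounds and Rayleigh monotonicity are verified against closed forms in the
tests.

## Determinism and problem sizes

Every stage derives its RNG from the master seed (`numpy.random.default_rng`
with fixed offsets), so a configuration reproduces byte-identical CSVs and
rasters. The shipped tests and the acceptance script run at desk scale —
64×64 to 128×128 grids, ≤ 2000 occurrences, ≤ 1000 bootstrap iterations —
sizes at which the full pipeline completes in seconds while still
exercising every code path at the default study conditions.

## Known limitations

* Averaged models lose exact partition additivity; the deviation is
  reported, not corrected.
* Rank-based component matching can mix components whose eigenvalues cross
  between bootstrap iterations.
* No spatially blocked cross-validation; background points are uniform
  in-mask samples, so evaluation AUC inherits presence-background caveats.
* Raster I/O is ESRI ASCII grid only; no reprojection or vector GIS.
* The chi-square HSI assumes the tail partitions are approximately
  independent unit-variance components; for heavy-tailed real data a
  min–max or empirical rescale may be preferable.
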