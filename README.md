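# ecominima

Species distribution modeling by **partitioned Mahalanobis D²**: find the
combinations of environmental conditions that vary *least* across a
species' occurrence sites — its *ecological minimums* — map a habitat
similarity index (HSI) from them, and model population connectivity by
circuit theory over the resulting resistance surface.

The package is aimed at spatial ecologists working with presence-only
occurrence data (the motivating system is greater sage-grouse leks on
1-km raster landscapes) who want a fully scripted, reproducible version of
this modeling chain, including a synthetic-landscape generator with a
*known planted niche* so every stage can be validated against ground truth.

## The model

Let x be the vector of p environmental variables at a landscape point, and
let μ and σ be the mean and SD of those variables over the n occurrence
sites. With z = (x − μ)/σ and R the occurrence correlation matrix with
eigenpairs (λⱼ, eⱼ), the Mahalanobis distance decomposes into p orthogonal,
additive *partitions*:

    D² = zᵀR⁻¹z = Σⱼ (eⱼ·z)² / λⱼ

Partitions with small eigenvalues (λ ≤ 1) are directions in which
occupied environments barely vary — interpreted as limiting requirements.
The reduced-rank statistic keeps only that minimum-variance tail,

    D²(k) = Σ_{j=k..p} (eⱼ·z)² / λⱼ,

and the habitat similarity index rescales it to [0, 1] through the
chi-square upper tail with df = p − k + 1, so HSI = 1 exactly at the
occurrence mean and decays monotonically. Fitting is bootstrap-averaged:
many per-population-capped resamples of the calibration occurrences, each
decomposed by PCA, components matched by eigenvalue rank and eigenvector
signs aligned before averaging.

For connectivity, cell resistance is the reciprocal of HSI scaled from 1
(HSI = 1) to 100 000 (HSI ≈ 0, and all cells outside the species' range);
each occurrence cell in turn injects a current equal to its mean annual
count while all other occurrence cells are grounded, and the per-solve
node currents are summed into a cumulative movement-potential map.

## Worked example

```python
import numpy as np
import ecominima as em

cfg = em.RunConfig(out_dir="demo_run", seed=7)   # 64x64 grid, p=10, 500 leks
res = em.run_pipeline(cfg)

print("k =", res.model.k_selected)
print("eigenvalues:", np.round(res.model.eigvals, 3))
print("median HSI  eval %.3f  historic %.3f" % (
    np.median(res.scores["evaluation"]), np.median(res.scores["historic"])))
print("AUC %.3f" % em.auc(res.scores["evaluation"], res.scores["background"]))
print("90%%-coverage HSI threshold %.3f" % res.threshold)
```

prints

```
k = 5
eigenvalues: [2.856 2.27  1.342 1.166 0.93  0.693 0.526 0.21  0.003 0.002]
median HSI  eval 0.419  historic 0.000
AUC 0.854
90%-coverage HSI threshold 0.052
```

The two planted minimum directions appear as the two near-zero eigenvalues
(0.003, 0.002); the boundary partition k = 5 is the first with eigenvalue
≤ 1. Held-out evaluation leks score a median HSI of 0.42 while degraded
historic locations score 0.0, and the model separates leks from random
background cells with AUC 0.85. The run directory contains the HSI and
cumulative-current rasters (ESRI ASCII), the fitted model JSON, and CSVs
of diagnostics per partition, dose-response curves, variable importance
and group summaries; re-running the same config reproduces them
byte-identically.

The same stages are available from the shell:

```
ecominima simulate --out sim --seed 7
ecominima fit --stack sim/stack --occurrences sim/occurrences.csv --out model.json
ecominima map --stack sim/stack --model model.json --out hsi.asc
ecominima connect --hsi hsi.asc --occurrences sim/occurrences.csv --out current.asc
```

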