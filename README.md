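# gslens

Influential-observation detection and outlier-aware genomic prediction for
high-dimensional marker data.

## The problem

Genomic selection (GS) predicts the genetic merit of breeding candidates —
their genome-estimated breeding values (GEBVs) — from genome-wide marker
panels where the number of markers *p* far exceeds the number of phenotyped
individuals *n*. A single contaminated phenotype record (a mistyped value, a
bad imputation, an off-trial observation) can distort every step of a
penalized fit: which markers are selected, how strongly effects are shrunk,
and ultimately the ranking of candidates. Classical single-model diagnostics
(Cook's D and relatives) do not transfer to the p ≫ n penalized setting, and
the leave-one-out LASSO diagnostics that do exist often disagree with one
another about which observations are influential.

`gslens` implements an integrated detector: four leave-one-out LASSO
influence diagnostics are each calibrated to a per-observation p-value, the
four p-values are fused by classical meta-analysis combiners into a single
p-value per observation, and observations below a cut-off (default 0.05)
are flagged. Flagged records can then be deleted or absorbed by a mean-shift
outlier model before refitting any of the standard GS predictors.

## The method

With the LASSO estimate
`argmin_b (1/2n) ||y − Xb||² + λ ||b||₁`
fitted over a decreasing λ grid with a K-fold cross-validation curve, four
per-observation case-deletion measures compare the full-data fit to the fit
without observation *i*:

| measure | change watched |
|---|---|
| `df_model` | selected variable set: size of the symmetric difference of the supports at the CV-chosen λ̂ |
| `df_lambda` | penalty choice: abs. log-ratio of λ̂ with and without *i* |
| `df_regpath` | coefficient path: mean normalized ℓ₂ distance along the λ grid |
| `df_cvpath` | CV error curve: mean normalized absolute distance along the grid |

Each measure is converted to a p-value by mid-rank empirical calibration
(large = influential), and the four p-values p₁..p₄ are combined per
observation by Fisher's inverse chi-square `L = Σ −2 ln p_k ~ χ²₂ₖ`, the
logit method `−Σ ln(p_k/(1−p_k))/C ~ t₅ₖ₊₄`, the mean-p statistic
`(0.5 − p̄)√(12K) ~ N(0,1)`, and Stouffer's weighted z
`Σ w_k z(p_k)/√(Σ w_k²) ~ N(0,1)`.

Downstream, the package provides LASSO, heritability-shrinkage ridge
(λ_r = m(1 − h²)/h²), RR-BLUP (REML through the spectral decomposition of
the marker kernel) and GBLUP with the VanRaden relationship matrix;
repeated 70/30 cross-validation reporting prediction accuracy
(r = S_{Y,Ŷ}/(S_Y S_Ŷ)) and MSE with standard errors; percentage
gain/reduction versus the untreated LASSO baseline; detector scoring with
precision, recall and F1 = √(precision × recall); and TOPSIS ranking of
competing methods. A synthetic-data generator (F2 genotypes on a Haldane
genetic map, additive QTL, target heritability, controlled ±3 SD phenotype
contamination) makes every stage testable without external data.

## Worked example

```python
import numpy as np
from gslens import (SimulationConfig, simulate_dataset, InfluenceConfig,
                    detect_outliers, delete_treat, LassoModel, cv_protocol,
                    pct_change, score_detector)

cfg = SimulationConfig(n_individuals=200, n_chromosomes=10,
                       markers_per_chromosome=100, heritability=0.5,
                       outlier_fraction=0.05, seed=7)
ds, truth = simulate_dataset(cfg)

table, combined = detect_outliers(
    ds.genotypes, ds.phenotype,
    InfluenceConfig(n_lambda=30, eps_ratio=0.1, k_folds=3, tol=1e-3, seed=7))
flagged = combined.flagged_set("fisher")
_, scores = score_detector(flagged, truth.outlier_indices, cfg.n_individuals)
print(f"flagged {len(flagged)}, recall {scores['recall']:.2f}, "
      f"precision {scores['precision']:.2f}")

lasso = lambda: LassoModel(n_lambda=30, eps_ratio=0.1, k_folds=3, tol=1e-3)
base = cv_protocol(ds.genotypes, ds.phenotype, lasso, n_rep=10, seed=1)
treated = delete_treat(ds.genotypes, ds.phenotype, flagged)
clean = cv_protocol(treated.X, treated.y, lasso, n_rep=10, seed=1)
gain, red = pct_change(clean, base)
print(f"accuracy {base.mean_accuracy:.2f} -> {clean.mean_accuracy:.2f} "
      f"(+{gain:.0f}%), MSE {base.mean_mse:.2f} -> {clean.mean_mse:.2f} (-{red:.0f}%)")
```

Output:

```
flagged 17, recall 1.00, precision 0.59
accuracy 0.37 -> 0.58 (+56%), MSE 6.50 -> 2.80 (-57%)
```

All ten injected outliers are recovered (seven clean observations are
co-flagged), and removing the flagged records raises held-out prediction
accuracy from 0.37 to 0.58 while cutting prediction error in half — contaminated
records do real damage to GEBV accuracy, and removing them recovers it.

The same workflow is scriptable from the shell:

```bash
gslens simulate --n 200 --h2 0.5 --outlier-frac 0.05 --seed 7 --out data/
gslens detect --genotypes data/genotypes.tsv --phenotypes data/phenotypes.tsv \
              --combine all --alpha 0.05 --out det/
gslens run --config run.yaml --out artifacts/   # full pipeline + TOPSIS ranking
```

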