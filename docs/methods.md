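# Methods

## Model and procedure

`gslens` treats outlier detection in genomic selection as a case-deletion
problem on a penalized regression. The phenotype model is the standard
additive marker model y = Xβ + e with n individuals and p ≫ n markers,
fitted by the LASSO

    β̂(λ) = argmin_β (1/2n) ‖y − Xβ‖² + λ ‖β‖₁

over a log-spaced decreasing grid from λ_max = max_j |x_j'y|/n (where every
coefficient is zero) down to a fixed fraction of λ_max, with a K-fold
cross-validation curve and λ̂ chosen at the CV minimum (a one-standard-error
rule is available). Columns of X are centered and scaled to unit variance
internally and y is centered; coefficients are reported on the original
scale. Monomorphic markers keep scale 1 and coefficient 0.

For each observation i the data are refitted without it, **on the same λ
grid**, and four diagnostics summarize how much the fitted object moved:

- `df_model` = |A △ A₍ᵢ₎|, the symmetric difference between the active sets
  at each fit's own CV-selected λ̂ (λ movement itself is `df_lambda`'s job);
- `df_lambda` = |ln λ̂₍ᵢ₎ − ln λ̂|;
- `df_regpath` = (1/L) Σ_λ ‖β̂(λ) − β̂₍ᵢ₎(λ)‖₂ / (1 + ‖β̂(λ)‖₂), computed on
  original-scale coefficients so the two fits' slightly different
  standardizations cannot register as influence;
- `df_cvpath` = (1/L) Σ_λ |CV(λ) − CV₍ᵢ₎(λ)| / (1 + CV(λ)).

All four are zero for a deletion that changes nothing. Leave-one-out CV
fold labels are the full-data labels with observation i dropped, so curve
differences reflect the deletion, not fold churn.

### P-value calibration

Measures are calibrated to per-observation p-values without a parametric
null, using exchangeability of uncontaminated observations. The default is
the **mid-rank empirical** rule

    p_i = (0.5 + #{j≠i : m_j > m_i} + 0.5·#{j≠i : m_j = m_i}) / n.

The strict variant p_i = (1 + #{j≠i : m_j ≥ m_i})/n is available
(`pvalue_method="empirical"`) but interacts badly with tie-heavy discrete
measures: `df_model` and `df_lambda` are exactly zero for most deletions, so
the strict rule assigns p = 1 to the modal mass, and after the clamp needed
by the logit/Stouffer transforms (p = 1 ↦ 1 − 1/(2n)) every such observation
contributes z ≈ −2.8 to the combined statistic. An observation that is
strongly influential on two measures and unremarkable on the other two is
then suppressed. The mid-p correction keeps the discrete null centered at
1/2 and restores the intended behaviour of the combiners; this is the
standard remedy for combining discrete p-values. A `robust_z` calibration
(upper-tail normal probability of the median/MAD z-score, falling back to
empirical when the MAD is zero) is offered for continuous measures.

### Combination and flagging

The four p-values per observation are fused under the classical
independent-uniform null by Fisher's inverse chi-square (χ²_{2K}), the
logit method with the Mudholkar–George scaling constant
C = √(K π² (5K+2) / (3(5K+4))) against t_{5K+4}, the mean-p statistic
(0.5 − p̄)√(12K) against N(0,1), and Stouffer's weighted z with upper-tail
quantiles z(p) = Φ⁻¹(1−p) so that small p_k always push the combined p
toward zero. Observations with combined p strictly below α (default 0.05)
are flagged. The four diagnostics are of course not independent; the
combiners implement the stated reference distributions as defined, and the
test suite documents their calibration (exactly uniform under an
independent null; conservative dependence effects are not corrected).

### Treatments and predictors

Flagged observations are either deleted (rows removed from X and y) or
absorbed by the mean-shift outlier model (MSOM). MSOM's `indicator` mode
appends one 0/1 column per flagged observation — its own fixed location
shift — which for dense least squares is algebraically identical to
deleting those rows (verified to 1e-10 in the tests). The `replace` mode
substitutes flagged responses with fitted values from a model trained on
the unflagged rows only (one fit excluding *all* flagged points, so that a
flagged point is never predicted from a fit still containing the other
outliers), then keeps all n rows.

Predictors share a fit/predict contract on raw genotype matrices:

- **LASSO**: effects at the CV-selected λ̂.
- **Ridge** with heritability-derived shrinkage λ_r = m(1 − h²)/h² on
  unit-variance markers; `lambda_override` bypasses the formula for
  identity checks.
- **RR-BLUP**: y = 1μ + Zu + e with u ~ N(0, σ²_u I) on standardized
  markers; REML via the eigendecomposition of ZZ' and a bounded 1-D search
  over ln(σ²_e/σ²_u) on [−12, 12] (49-point bracketing grid, then Brent to
  1e-8). The reported heritability estimate is σ̂²_u·mean(diag ZZ') /
  (σ̂²_u·mean(diag ZZ') + σ̂²_e), which reduces to the familiar
  σ²_u m/(σ²_u m + σ²_e) for unit-variance markers.
- **GBLUP**: y = 1μ + g + e with g ~ N(0, G σ²_g), G the VanRaden method-1
  matrix WW'/(2Σp_k(1−p_k)) with frequency-centered dosages; REML on the
  training block and genetic values for unphenotyped individuals through
  the G cross-block (conditional expectation). {0,1} presence/absence
  markers (DArT panels) run through the same formulas as two-level dosages.

Evaluation follows the repeated-split protocol: 70 % training / 30 %
testing, default 100 replicates, per-replicate accuracy r (Pearson
correlation of observed and predicted phenotype) and MSE, aggregated with
standard errors; treatments are applied to the full dataset *before*
splitting. Methods are compared as percentage gain in accuracy and
percentage reduction in MSE versus the untreated LASSO baseline (labeled
`LASSO*`, whose own gain/reduction is blank). Detector output is scored
against the simulation truth by precision, recall and F1; the headline F1
is the geometric mean √(precision × recall) — matching the defining formula
and the published score tables — with the harmonic variant also emitted
(`f1_harmonic`), and 0/0 cases resolve to 0. TOPSIS ranks methods by
closeness C = d⁻/(d⁺ + d⁻) after vector normalization and weighting, with
impacts + for accuracy and − for MSE and both standard errors, equal
weights by default.

## Synthetic data generator

The generator emulates an F2 experimental cross, the design under which the
detector is benchmarked:

- **Genotypes**: `n_chromosomes` × `markers_per_chromosome` biallelic
  markers equi-spaced on chromosomes of `chromosome_length` cM (defaults
  10 × 100 on 100 cM). Each individual inherits two independent gametes;
  each gamete's allele sequence is a first-order Markov chain with
  recombination probability r = (1 − e^(−2d/100))/2 (Haldane) between
  adjacent markers. Dosages are {0,1,2} with 1:2:1 marginals; markers at
  identical positions are perfectly linked.
- **Phenotype**: `n_qtl` QTL (default 10, spread round-robin over
  chromosomes at random marker positions) with N(0, `qtl_effect_scale`²)
  effects in centered Cockerham coding g = Σ a_q (x_q − 1); residual
  variance Var(g)(1 − h²)/h² so realized Var(g)/Var(y) targets the
  configured heritability (0.1 / 0.5 / 0.7 in the benchmark settings).
- **Contamination**: round(fraction·n) randomly chosen phenotypes (5 % by
  default, round-half-up) replaced by μ + s(margin + u)σ with random sign
  s, u ~ U(0,1), μ and σ from the pre-contamination vector — every
  contaminated value exceeds the ±3 SD margin strictly but boundedly, and
  the contaminated indices plus original values are recorded as ground
  truth.

One integer seed drives a single generator stream per dataset.

What the generator does **not** emulate: dominance/epistasis, missing
genotypes, multi-environment or repeated-measures structure, population
structure/relatedness beyond the F2 design, and non-Gaussian phenotype
error. Passing tests therefore demonstrate detector behaviour under clean
additive architecture with gross symmetric contamination; real panels
(where outliers may be milder, asymmetric, or correlated with structure)
can only be harder.

## Numerical choices

- **Solver**: cyclic coordinate descent (numba kernel) with pathwise warm
  starts and the glmnet-convention duality-gap stopping rule
  (gap ≤ tol·‖y‖², default tol 1e-4). A coefficient-change criterion is
  impractical here: at small λ with p > n and strong marker linkage the
  objective converges orders of magnitude faster than the (nearly
  non-identified) coefficients. The kernel accepts per-λ warm starts from
  a reference path; a leave-one-out refit starts at the full-data solution
  and typically converges in a few sweeps. Correctness is cross-checked
  against an independent coordinate-descent implementation
  (scikit-learn's), against the orthonormal-design closed form (1e-8),
  against KKT conditions (1e-6) and against brute-force sign-pattern
  enumeration on tiny instances.
- **LOO bookkeeping**: the fold whose test split contains the deleted
  observation has an unchanged training set, so its reference fit is
  reused and only that observation's residuals leave the curve; the other
  K−1 folds are refitted warm from their reference fits. Results are
  independent of evaluation order and bit-reproducible given the seed.
- **REML**: eigendecomposition once per fit, profiled restricted
  likelihood in the rotated basis, variance components non-negative by
  construction; a 1e-8-scaled diagonal jitter retry (logged) guards
  near-singular kernels.
- **Ties and boundaries**: flagging uses strict p < α; empirical p-values
  never reach 0; p = 1 (possible under the strict empirical rule) is
  clamped to 1 − 1/(2n) for the logit/Stouffer transforms with a logged
  warning; TOPSIS breaks closeness ties by stable sort order.
- **Grids**: engine defaults are 100 λ values down to 1e-3·λ_max and
  K = 10 folds.

### Problem sizes for repeated study-scale runs

The acceptance checks and the heavier tests run the full detector on many
replicate datasets at the benchmark scale (n = 200, p = 1000). For those
repeated runs the package uses a reduced profile — 30 λ values down to
0.1·λ_max, 3 CV folds, solver tol 1e-3 — chosen for cost: marker linkage
makes deep λ grids disproportionately expensive, and the CV-selected λ̂ was
verified to sit in the interior of the shallower grid (never at its floor)
across seeds and heritability levels before adoption. Detector recall
under this profile reproduces the published benchmark level (≈ 0.8 at
h² = 0.1). Stochastic checks use 10 replicate datasets for the recall
benchmark and 20 for the end-to-end improvement property, with 5–10 CV
replicates per arm.

## Design choices where the design was open

- The four diagnostics are named in the source material but their formulas
  are not printed there; the definitions above are this package's
  contract: zero-compatible, scale-normalized, computable from path/CV
  objects. Exact agreement with any external implementation is not
  claimed, and benchmark comparisons are made at tolerance, not equality.
- `df_model` compares supports at each fit's own λ̂ rather than at a common
  λ, since λ movement is measured separately.
- No multiplicity correction is applied across the n observations; the
  cut-off is a fixed per-observation α = 0.05, matching the benchmark
  protocol. FDR-style control is out of scope.
- Which mean-shift variant ("indicator" vs "replace") underlies published
  whole-set accuracy figures is ambiguous; both are implemented and the
  choice is an explicit, logged option (`indicator` is the default, being
  the statistically defined mean-shift model).
- QTL number, effect distribution and chromosome length are not fixed by
  the benchmark description; defaults (10 QTL, N(0,1) effects, 100 cM) are
  exposed in `SimulationConfig`. Heritability is the controlled quantity,
  so effect scale is immaterial after residual-variance calibration.

## Known limitations

- Leave-one-out refits cost n × K path fits; for n in the thousands a
  screening or approximate-LOO strategy would be needed.
- Empirical calibration bounds p-values below by ~1/(2n), which caps the
  evidence any single measure can contribute; with very small n the
  combined p cannot reach extreme significance.
- The combiners assume independent p-values; the four diagnostics are
  positively dependent, making the combined test conservative at fixed α
  rather than exact.
- GBLUP prediction for unphenotyped individuals uses training-set allele
  frequencies; strong train/test frequency drift (not present in random
  splits) would bias the cross-block.
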