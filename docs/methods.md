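# Methods

## The estimation problem

Mendelian randomization treats genetic variants as instrumental variables
for the causal effect of an exposure X on an outcome Y.  The structural
model is linear:

    Y = β₀ X + U,        E[U | Π, Z] = 0
    X = Z Π + V,         E[V | Z] = 0

with Z an N × Υ dosage matrix and (U, V) correlated errors whose
covariance σ_UV is the confounding that invalidates the naive regression
of Y on X.  Two-stage least squares (2SLS),

    β̂ = [XᵗZ(ZᵗZ)⁻¹ZᵗX]⁻¹ XᵗZ(ZᵗZ)⁻¹ZᵗY,

is consistent when the instruments are valid, but in one-sample practice
the instruments are themselves *estimated* from the same data (a GWAS of
X plus a predictor fit), and the leading bias of the resulting estimator
is proportional to (Υ/N)·σ_UV (the Nagar approximation, exposed as
`nagar_bias_term`).  This endogeneity bias — weak-instrument bias plus
winner's curse — points *toward* the confounded association, which is the
dangerous direction: it inflates type-I error.

## Cross-fitted instruments

The package's core replaces the in-sample first stage with K-fold
cross-fitting.  The indices are partitioned into folds I₁…I_K of
near-equal size.  For each fold k a predictor of the exposure is built on
the complement I_kᶜ (association scan → greedy r² clumping → strict
P-value filter → L1-penalized fit with cross-validated penalty), and each
individual in I_k receives the prediction of the model that never saw
them.  Concatenating the per-fold predictions gives the length-N
cross-fitted instrument X̆.  Because individual i's instrument value is a
function of Z_i and of *other* individuals' data only, the instrument
construction noise is independent of U_i, and the endogeneity term
vanishes by design.  What remains is a classical errors-in-variables
attenuation: the estimator is, at worst, biased toward zero —
conservative — and the bias decays as the sample grows.

Two estimators consume X̆:

* **CFMR1** (`cfmr1`): the equal-weight average of per-fold 2SLS
  estimates, each fold instrumented by its own out-of-fold prediction.
* **CFMR2** (`cfmr2`): a single 2SLS of the full data on X̆.  The two are
  asymptotically equivalent; CFMR2 has better finite-sample behavior and
  is the recommended default.

The K = N limit with leave-one-out least-squares predictors reproduces
the Jackknife IV estimator exactly (covered by a test against an
independent leave-one-out implementation).

## Conventions and numerical choices

* **Fold sizes.** When K ∤ N the first (N mod K) folds receive one extra
  element.  Folds are drawn uniformly from a seeded generator.
* **No re-centering.** X̆ concatenates raw per-fold predictions; fold-mean
  offsets are part of the instrument.  With fully degenerate
  (intercept-only) folds the offsets are all the variation that remains,
  and the estimator's conservativeness is the safety net.
* **Standard errors.**  The homoskedastic second-stage formula: residuals
  e = Y − Xβ̂ in the residualized frame, σ̂² = eᵗe/(n − q − 2) with q
  covariates, Var(β̂) = σ̂²·[XᵗZ(ZᵗZ)⁻¹ZᵗX]⁻¹.  A heteroskedasticity-
  consistent sandwich variant sits behind `robust=True`.  CFMR1's variance
  treats folds as independent (Var = ΣVar_k / K²), which is approximate
  because training complements overlap; CFMR2 is preferred partly for
  this reason.  Confidence intervals are Wald at 95% (z = 1.959964);
  p-values are two-sided normal.
* **Covariates.** Exposure, outcome and instrument are residualized on
  [1, covariates] before 2SLS (Frisch–Waugh), equivalent to carrying the
  covariates through both stages.  In the instrument-building scan,
  covariates are residualized out of both dosage and exposure.
* **Clumping.** Variants are processed in ascending p-value (ties broken
  by column index); a variant is kept iff its squared dosage correlation
  with every retained variant inside the window is below the threshold
  (default r² = 0.1; window infinite unless positions are given, default
  500 kb in the CLI).  The held-out "variance explained" diagnostic is the
  squared Pearson correlation of X̆ with X, reported as a percentage.
* **Degenerate folds.** A fold whose selection is empty or whose
  penalized fit shrinks every coefficient to zero yields an intercept-only
  prediction and is flagged.  `build_cfi` always returns the (flagged)
  instrument; `cfmr1` raises when no fold identifies the effect, `cfmr2`
  raises only when X̆ has zero variance.  The scenario driver records such
  replicates as failures rather than dropping them.

## The penalized predictor

The per-fold predictor is an L1-penalized linear fit on standardized
dosages with the penalty chosen to minimize cross-validated prediction
error.  The solver works on Gram matrices (ZᵗZ, Zᵗx accumulated once per
fold) with warm-started cyclic coordinate descent along a geometric
penalty path; agreement with scikit-learn's `Lasso` on explicit data is
part of the test suite.  Defaults inside the cross-fitting driver: a
30-point path from the null penalty down to 2% of it, coordinate
tolerance 1e-4, and — when 3 ≤ K ≤ 21 — the K−1 co-folds of the partition
reused as CV splits (deterministic, and the fold Gram matrices are already
available).  The standalone `fit_predictor` defaults to 10 random CV
splits with a denser path (100 points to 0.1%).  The 2% penalty floor
matches the regime of sparse genetic architectures, where informative
penalties sit near the noise level of marginal correlations, well above
that floor; the flat dense tail of the path costs cubic time and is never
selected by CV in this regime.  CV fold Grams reuse the training block's
centering (exact Gram subtraction), and each fold's training statistics
are assembled from prefix/suffix sums over the *other* folds, so a fold's
own data never touches its predictor even at the bit level.

Alternatives: `least-squares` (unpenalized fit on the selected variants),
`allele-score` (marginal scan slopes as fixed weights — a PRS-style
instrument), and a `fixed` oracle hook that evaluates a supplied affine
map in every fold (used by tests).

## Synthetic cohorts

`simdata` draws independent biallelic variants as Binomial(2, maf)
dosages (Hardy–Weinberg, no LD — the reference designs state independent
variants), gives the first `n_causal` columns a common effect π, and
draws (U, V) from a bivariate normal.  π is calibrated in closed form so
the causal variants explain exactly the requested fraction h² of the
exposure variance:

    π = sqrt( h²·σ_V² / ((1 − h²)·n_causal·2·maf·(1 − maf)) ).

Genotypes are unstandardized dosages {0,1,2}; variance-explained
statements are honored through this calibration.  Reference scenario
values: 300 variants, 5 causal, maf 0.3, σ_U² = σ_V² = 5, σ_UV = 0.8
(moderate confounding) or 4.9 (near-perfect error correlation, the
overlap-bias stress test), effects β₀ ∈ {0, ±0.05, ±0.08}, K = 10 folds.
What this generator does *not* emulate: linkage disequilibrium, allele-
frequency spectra, assortative mating, pleiotropy, binary traits, or
population stratification within a stratum — so passing tests certify the
estimator's behavior under the stated structural model, not robustness to
those real-data complications.

Each dataset is regenerable bit-for-bit from one integer seed; scenario
grids derive replicate r's data seed as base_seed + r, with partition and
CV seeds spawned from an independent stream so fold draws never reuse
genotype randomness.  Cells differing only in β₀ share all draws
(Y = β₀X + U with X, U β₀-free), so the driver builds each replicate's
instrument once and reuses it across the β₀ grid; method contrasts are
within-replicate by construction.

## Evaluation and the power benchmark

`run_scenario_grid` records per-replicate estimates, SEs and p-values and
summarizes mean estimate, empirical SD, mean reported SE, rejection rates
and failure counts per cell.  The closed-form comparator
`theoretical_power_2smr` uses the asymptotic standard error
SE∞ = sqrt(σ_U²/(n·h²·Var X)) and two-sided normal rejection — the
standard large-sample power of a two-sample MR with an instrument
explaining h² of the exposure.  At the reference design (N = 10,000,
h² = 20%, Var X = 6.25, σ_U² = 5) SE∞ = 0.02.

Desk-scale problem sizes: the acceptance checks run 200–300 replicates at
N between 1,000 and 10,000 with the full 300-variant panel, and the
reproduction script uses N = 2,000–5,000 with 150–200 replicates; the
original study conditions (up to 500,000 individuals and 1,000
replicates) are available through the same configuration objects.

## Cross-population pooling

`cross_population_cfmr` runs the entire pipeline independently within
each population stratum and pools stratum estimates with fixed-effect
inverse-variance weights (w_i = 1/se_i²); Cochran's Q is reported so a
violated shared-effect assumption is visible.  Fixed-effect (not
random-effects) pooling is deliberate: the target is a single shared
causal effect, and heterogeneity should be diagnosed, not averaged away.
Strata below a configurable size floor (default 100) are excluded with a
warning.  The pooled SE never exceeds the smallest stratum SE (an
algebraic identity of the weighting).

## Known limitations

* Validity relies on no pleiotropy and a linear first stage; neither is
  tested for.  Non-linear exposure predictors would slot in as
  alternative `method` values but are not implemented.
* The CFMR1 variance treats folds as independent; it is mildly
  mis-calibrated and kept mainly for completeness.
* Reported SEs are conservative at small N (≤ 10,000), so type-I error
  control is tighter than nominal at the cost of some power — visible in
  the SE-vs-empirical-SD comparison of the evaluation output.
* VCF import takes GT-derived alternate-allele counts only; dosage (DS)
  fields, missing genotypes and multiallelic records are rejected.
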