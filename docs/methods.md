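# Methods

This document records the statistical model, the algorithms, the default
parameter choices, and the known limitations of `gmdrpower`.

## 1. Generative model

A subject has genotypes at `m` biallelic markers (coded 0/1/2 = minor-allele
count), an optional continuous covariate `e`, and a binary phenotype `y`.

* **Genotypes**: Hardy–Weinberg proportions per locus
  `((1−q)², 2q(1−q), q²)` at minor allele frequency `q ∈ (0, 0.5]`, loci in
  linkage equilibrium. Functional loci are by convention the first `k`
  markers of the panel; the remaining markers are noise.
* **Covariate**: `e ~ Normal(0, σ_E²)`, independent of genotype.
* **Penetrance** (probability of disease):

  `π(g, e) = expit(β₀ + β_G·x_G(g) + β_E·e)`

  where `x_G(g) ∈ {0,1}` indicates membership of the high-risk genotype
  set of the chosen epistasis model:

  | model | loci `k` | high-risk set | prior mass at MAF 0.5 |
  |---|---|---|---|
  | `checkerboard` | 2 | exactly one heterozygous locus | 1/2 |
  | `3ULM` | 3 | exactly 3 major alleles among 6 | 20/64 |
  | `4ULM` | 4 | exactly 4 major alleles among 8 | 70/256 |

  All three are "interaction-only" patterns: marginal single-locus
  effects are weak by construction.

**Defaults** (the reference configuration used throughout the tests and
the CLI's `--cov-sd auto`): `β₀ = −5.30`, `β_E = 1`, `β_G ∈ {1.0, 1.5,
2.0, 2.5}`, `m = 10` markers. All quantities are unitless probabilities
or logistic coefficients.

### Covariate-SD calibration

`analytic.calibrate_covariate_sd` chooses `σ_E` so the
covariate-integrated group penetrances

`pen(x_G) = ∫ expit(β₀ + β_G·x_G + β_E·e) φ(e; 0, σ_E²) de`

hit two targets (bounded 1-D minimization on `σ_E ∈ [0, 20]`, tolerance
1e-8; an unachievable target pair raises `CalibrationError`). For the
reference configuration with targets `(0.073, 0.221)` this gives
`σ_E ≈ 3.180`, population prevalence `K = Σ_g P(g)·pen(g) ≈ 0.147`.
Integrals over `e` use 128-node Gauss–Hermite quadrature everywhere.

## 2. Residual scores and the GMDR/MDR engine

* **Scores**: fit the null logistic model (intercept + covariates, no
  genotype terms; `statsmodels` GLM/IRLS) and set `s_i = y_i − π̂_i`.
  Cases score positive, controls negative, and `Σ s_i = 0` exactly by
  the score equations. Non-convergence or (quasi-)separation raises
  `ScoringError`. Without covariates `π̂` is the sample prevalence, so a
  balanced design gives `s_i = ±0.5` and the engine is exactly classic
  count-based MDR (verified against an independent count-based oracle in
  the test suite).
* **Cells and labels**: for a candidate `k`-locus combination, subjects
  are binned into the `3^k` genotype cells; a cell is **high-risk** iff
  its *average* score `≥ T` with `T = 0` (boundary ties go high). Cells
  unseen in training are treated as low-risk at evaluation.
* **Accuracy**: score-mass confusion — `TP` = positive score mass in
  high cells, `TN` = |negative| mass in low cells, etc.; accuracy =
  `(TP+TN)/(TP+TN+FP+FN)`.
* **Cross-validation**: stratified 10-fold (default) partition; within
  each fold the exhaustive search over all `C(m,k)` combinations
  maximizes training accuracy (first-in-lexicographic-order wins ties);
  the winner's testing accuracy (TA) on the held-out fold is recorded.
  Per order, the **final model** is the modal winner across folds and
  **CVC** is its fold count. Across orders, the order maximizing mean TA
  is selected unless it disagrees with the order maximizing CVC, in
  which case the *lower* of the two orders wins (parsimony rule).
* **Implementation**: the search is vectorized (per-combination flattened
  cell offsets + `bincount` of signed score masses), giving ~17 ms per
  full 45-pair 10-fold search at n = 2000.

## 3. Theoretical accuracy

For study design the package computes the large-sample limit of the
engine's accuracy directly from the model.

* **Conditional genotype distributions** (Bayes):
  `P(g|case) = P(g)·pen(g)/K`, `P(g|control) = P(g)(1−pen(g))/(1−K)`.
* **Genotype-based (unadjusted) accuracy** for a balanced sample: label
  `g` high iff `½P(g|case) ≥ ½P(g|control)`; accuracy =
  `½·Σ_high P(g|case) + ½·Σ_low P(g|control)`. For the reference
  checkerboard configuration this is **0.648**.
* **Score-based (adjusted) accuracy**: the population limit of what GMDR
  computes with covariates. First the probability limit `(β₀*, β_E*)` of
  the null logistic fit in a balanced *ascertained* sample is obtained by
  maximizing the expected log-likelihood
  `½·E[ℓ | case] + ½·E[ℓ | control]` over the Bayes posterior of `e`
  given status and genotype (quadrature + BFGS with analytic gradient).
  Expected positive/negative score masses per cell and status then
  follow, cells are labeled by the sign of their expected mean score,
  and accuracy is the correctly-labeled score mass fraction. For the
  reference configuration this is **0.746**: covariate adjustment
  recovers classification signal that the covariate noise hides from the
  unadjusted statistic.
* **Heritability** (variance-explained / Culverhouse-style):
  `h² = Σ_g P(g)(pen(g) − K)² / (K(1−K))`; **0.0437** for the reference
  configuration.

## 4. Simulator

`simulate_case_control` draws population subjects `(g, e, y)` from the
generative law in vectorized batches and keeps the first `n/2` cases and
`n/2` controls (rejection sampling, budget 10⁷ draws; arms are then
shuffled together). This samples the exact conditional laws
`P(g, e | y)`, which the test suite verifies against the analytic
conditionals by pooled chi-square. The realized population prevalence is
reported alongside the dataset.

## 5. Permutation threshold and power

* **Null distribution**: for one representative dataset of the scenario,
  shuffle the residual scores (GMDR) or equivalently the phenotype (MDR)
  `n_perm` times; each pseudo-sample undergoes the *complete*
  cross-validated search, contributing its selected model's mean TA.
  This builds the multiple-testing-corrected null of the best-model TA.
* **Threshold**: the empirical `(1−α)` quantile via the conservative
  order statistic `⌈(1−α)(n_perm+1)⌉` — the 951st smallest of 1000 null
  TAs at `α = 0.05`.
* **Power**: simulate `n_replicates` independent datasets; a success
  requires the selected model to be exactly the true functional set
  *and* its mean TA to strictly exceed the threshold. Replicates where a
  wrong model clears the threshold are tallied separately
  (`wrong_significant_fraction`). The threshold is derived once per
  scenario. `run_grid` evaluates scenario × method grids with JSON
  checkpointing and per-scenario failure flagging.

Reproducibility: every stochastic component takes an integer seed and
derives independent sub-streams via `numpy` `SeedSequence` lists; equal
seeds give bit-identical results on a fixed dependency stack.

## 6. Default problem sizes

The shipped acceptance script (`scripts/acceptance.py`) uses desk-scale
runs chosen to finish in minutes on one CPU: power at 100 replicates ×
1000 permutations (n = 2000), calibration at 200 replicates × 1000
permutations (n = 1000). These are the package's own scaled-down
defaults; full design grids (many scenarios × 200 replicates × 1000
permutations) are supported via `run_grid` but are compute-hours-scale.

## 7. Known limitations and discrepancies

* **Accuracy–heritability correlation**: across the 12 trigenic (3ULM)
  scenarios (MAF ∈ {0.1, 0.25, 0.5} × β_G ∈ {1.0, 1.5, 2.0, 2.5}) this
  implementation obtains Pearson r = **0.935** over all 12 points,
  rising to **0.952** when near-chance points (accuracy < 0.52) are
  excluded. Reference values quoted for this quantity elsewhere (~0.89
  for all points, ~0.95 after exclusion) could not all be reproduced
  from the stated inputs: the exclusion-filtered value and the analogous
  checkerboard correlation (~0.98) match, but the all-points 3ULM value
  does not, under any rounding or heritability-definition variant we
  tried. The corresponding acceptance test is expected to fail and is
  kept honest rather than tuned.
* **Wrong-model significance rate**: at the shipped calibration scenario
  the fraction of replicates in which a *wrong* model clears the 5%
  threshold is ~0.005, not ~0.05. When the selected model is usually the
  true one, wrong-model exceedances are necessarily rare; a ~5% rate is
  what aggregation over many low-power scenarios yields. The
  corresponding acceptance test compares against 0.05 and may fail; the
  type-I calibration of the threshold itself (overall exceedance rate ≈
  α under β_G = 0) is verified separately and passes.
* The adjusted-score accuracy construction (Section 3) is this package's
  own population-limit derivation; it reproduces the reference value
  0.743 within 0.003.
* Single normal covariate in the generative model (the analysis engine
  accepts any number of covariates); no family-based designs; no
  genome-wide panels (exhaustive search is combinatorial in `m`).
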