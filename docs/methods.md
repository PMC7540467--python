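# Methods

This note records the statistical models implemented in `qstfst`, the
numerical choices behind them, and what the simulation-based tests do and
do not establish.

## Neutral differentiation (module `fst`)

Theta follows Weir & Cockerham (1984) extended to arbitrary numbers of
alleles: for each locus and each allele the among-population component `a`,
the between-individual-within-population component `b`, and the
within-individual component `c` are computed from the per-population allele
frequencies, observed heterozygote frequencies, and sample sizes; the
multi-locus estimate is the ratio of sums over all loci and alleles.
Choices:

* Missing calls are removed per individual and locus, so sample sizes are
  per-locus.  A locus observed in fewer than two populations, or
  monomorphic overall, contributes nothing (0/0) and is skipped.
* Negative theta values (sampling noise around zero differentiation) are
  reported as computed.  They are clamped to zero only where a downstream
  formula requires non-negativity: the isolation-by-distance linearization
  `F/(1−F)` and the neutral-null scaling `2F/(1−F)` (the floor there is
  1e-6 because the scaling is undefined at 0), each with a warning.
* The permutation test for the overall theta permutes whole individuals
  (both alleles move together, preserving within-individual disequilibrium)
  among populations with population sizes fixed, and uses the add-one
  estimator `p = (1 + #{θ* ≥ θ}) / (n_perm + 1)`.
* Gene diversity is the unbiased expected heterozygosity
  `Hs = n/(n−1)·(1 − Σp²)` per population, averaged over populations with
  allele-count weights.

## Variance components, h² and Q_ST (module `quantgen`)

The per-trait model is `y = μ + population + family(population) + block +
ε` with independent zero-mean Gaussian effects and homogeneous variances.
The REML engine (internal module `_mixed`) profiles the residual variance
and maximises the restricted likelihood over the variance *ratios*
`γ_k = σ_k²/σ²` with L-BFGS-B under a zero lower bound, using an analytic
gradient assembled from a Cholesky factorisation of the q×q matrix
`I + D Z'Z D` (q = total random-effect levels), never an n×n matrix.  The
response is centred and standardised internally — the ratios are
scale-free — so trait units cannot affect conditioning, and translation or
rescaling of a trait provably leaves h² and Q_ST unchanged.  Convergence
tolerance is 1e-10 on the criterion with two starting points (ratios 0.5
and 0.05); estimates can sit exactly on the zero boundary.  The criterion
value matches lme4's REML log-likelihood convention (verified in the test
suite against `lmer` through Rscript).

* **Component significance.**  Each component is tested with a boundary
  likelihood-ratio test against the model with that component removed
  (identical fixed part); the statistic is referred to the
  `0.5·χ²₀ + 0.5·χ²₁` mixture.  A component with `p ≥ α` (default
  α = 0.05, configurable) is treated as null in downstream formulas; the
  other estimates are kept from the full fit.
* **Heritability.**  `h² = 2·V_w/(V_w + V_res)` for full sibs, estimated on
  all families of a subspecies at once.  Values above 1 (possible when the
  family variance exceeds the residual) are reported with a warning rather
  than clamped, because Q_ST cancels h² algebraically and clamping would
  silently change it.
* **Q_ST.**  `Q_ST = V_b/(V_b + 2·h²·(V_w + V_res))`, which with the
  full-sib h² from the same fit reduces exactly to `V_b/(V_b + 4·V_w)`;
  the test suite asserts the two forms agree to 1e-12.
* **Pairwise Q_ST.**  Each population pair is refitted on its own data
  after a square-root normalisation of the trait; when negative values
  exist the trait minimum is first shifted to zero (the transform is
  otherwise a plain square root).  The overall Q_ST uses untransformed
  data.  The subspecies-level h² is shared across all pairs.  Pairs whose
  fit fails yield missing entries rather than aborting the matrix.
* **Confidence intervals.**  Parametric bootstrap: datasets are simulated
  from the fitted model on the observed design (population, family, block
  and residual draws with the estimated variances), refitted by the same
  REML machinery, and the statistic's 2.5/97.5 percentiles reported.
  Non-converged replicates are dropped and counted, with a warning above
  10%.  Default 1,000 replicates.
* Missing trait values are removed listwise per trait; the model is
  univariate throughout (no genetic correlations, no pedigree BLUP).

## The neutral null for Q_ST − F_ST (module `compare`)

Two decision rules per trait.  The CI-overlap rule is immediate: neutral if
the Q_ST bootstrap CI contains the mean F_ST, divergent if F_ST falls below
it, stabilizing if above.

The simulated null asks how far `Q_ST − F_ST` can wander under pure drift
given this study's actual sampling design.  Each replicate:

1. resamples loci with replacement and recomputes the ratio-of-sums theta,
   propagating marker sampling error (resampled values at or below 0 are
   floored at 1e-6; values at or above 1 trigger a redraw, counted and
   reported);
2. draws the within-population additive variance `V_A = 2·V_w` from a
   parametric-bootstrap cache of family-component refits (default 1,000
   refits, resampled inside the replicate loop rather than refitting per
   replicate — the distribution is the same and the cost is bounded);
3. sets the true neutral among-population variance to
   `V_b = 2·F/(1−F)·V_A`, the level at which the expected Q_ST equals F_ST;
4. re-estimates the components from the simulated values: with a balanced
   nested design the estimator `V̂_b = (MS_pop − MS_fam)/(s·f̄)` has
   `MS_pop ∼ E[MS_pop]·χ²_d/d` (d = n_pops − 1, carrying both the
   finite-deme sampling and the estimation noise) and
   `MS_fam ∼ E[MS_fam]·χ²_{n_fam−n_pops}/(n_fam−n_pops)`;
   `V̂_A = 2·(MS_fam − MS_res)/s` shares the same `MS_fam` draw, which
   preserves the negative correlation between the numerator and the
   denominator of Q_ST.  Negative component estimates are floored at zero,
   as in the observed fit;
5. records `V̂_b/(V̂_b + 2·V̂_A) − F*`.

The re-estimation step matters: without it the null carries only the
deme-sampling and locus-resampling spread, while the observed difference
also carries REML estimation noise, and the test rejects a neutral trait
far too often (empirically ~40% at α = 0.05 on an 8-population design;
with re-estimation the measured type-I error is 2–7%, see the acceptance
results).  Drawing the mean squares from their chi-square sampling
distributions is distributionally equivalent to simulating a full dataset
and refitting, at a vectorisable cost, so the 100,000-replicate null the
procedure calls for is practical; the package default is 10,000 with the
full size one argument away.

The p-value is two-tailed with the add-one correction,
`p = 2·min[(1 + #{null ≥ d})/(n+1), (1 + #{null ≤ d})/(n+1)]` capped at 1;
whether one or two tails is appropriate is genuinely open, and two tails is
the conservative choice for a test that looks for departures in either
direction.

## Divergence statistics (module `divergence_stats`)

Population effects per subspecies are tested by maximum-likelihood (not
REML, since the fixed parts differ) fits of `y ~ population + (block)`
against `y ~ 1 + (block)`, with the statistic referred to χ² on
n_pops − 1 degrees of freedom.  Marginal means are the per-population
fixed-effect estimates of the same model fitted by REML (cell-means
parameterisation, model-based standard errors), i.e. population means with
the container effect averaged out.  Trait–altitude clines are ordinary
least-squares regressions of those marginal means on altitude in metres,
two-sided slope test.  The subspecies/population partition is a Gaussian
linear model with sequential (type-I) sums of squares — subspecies first,
then population nested in subspecies — reporting each term's share of the
total sum of squares and its F-test p; F tests were chosen over deviance
tests because the models are Gaussian and the quantities reported are R²
shares.

## Mantel tests (module `matrix_tests`)

The Mantel statistic is the Pearson correlation of the upper-triangle
entries; the null permutes rows and columns of one matrix simultaneously
while the other stays fixed.  With 7 or fewer populations all n!
relabelings are enumerated and the p-value is the exact proportion at
least as extreme, identity included — with five populations the smallest
attainable one-tailed p is therefore 1/120 ≈ 0.008.  Above n = 7 a seeded
sample of permutations is drawn with the add-one correction.  The default
tail is `greater` (positive association), configurable; the partial Mantel
statistic is the first-order partial correlation
`(r_AB − r_AC·r_BC)/√((1−r_AC²)(1−r_BC²))` with the null permuting the
first matrix and recomputing the statistic.  Geographic distances are
haversine great circles with Earth radius 6,371 km; isolation by distance
uses `F/(1−F)` against log distance, rejecting zero distances.

## Synthetic data (module `synthetic_data`)

The generator emulates a two-subspecies common-garden study: 8 + 5
populations, 9–42 full-sib families per population, two sibs per family,
40 containers of 24 plants filled by randomized permutation, altitudes
uniform on 61–1,564 m, and 23 multi-allelic markers (3–12 alleles) under
the Balding–Nichols F-model at a target F_ST of 0.10.  Traits follow the
additive random-effects model the analysis assumes, with an optional
linear altitude cline on population means; a trait can instead draw its
among-population variance from the neutral model
`2F/(1−F)·V_A·χ²_d/d`, which is what makes the end-to-end type-I
calibration of the comparison testable.  Genotypes and phenotypes are
statistically independent, matching the neutral-marker assumption.

What the generator deliberately does not emulate: stepwise microsatellite
mutation (so R_ST-style statistics are out of scope), null alleles and
genotyping error, spatial autocorrelation of allele frequencies,
non-Gaussian trait distributions, genotype–environment interaction, and
marker–trait linkage.  Passing tests therefore demonstrate estimator and
test correctness under the assumed model, not robustness to those
violations.

## Validation experiments (module `calibration`, `scripts/acceptance.py`)

Each experiment regenerates data from scratch and summarises one property.
Replicate counts are chosen so the whole set runs in a few minutes on one
CPU; all sizes are function arguments.

| quantity | design | expectation |
|---|---|---|
| mean theta | 20 panels, 8 pops × 30 diploids × 23 loci, F = 0.10 | within 0.10 ± 0.02 |
| mean Q_ST | 100 studies, 8 pops × 25 families × 2 sibs, 40 blocks, true Q_ST = 0.3 | within [0.2, 0.4] |
| REML vs ANOVA | balanced 5 pops × 8 families × 2 sibs, no block variance | ≤ 1e-6 |
| type-I error | 200 neutral trials, 8 pops × 8 families, null of 2,000 replicates, V_A cache of 50 refits | within [0.01, 0.09] at α = 0.05 |
| Mantel gap | n = 4 matrices, 10,000 sampled vs 24 exact permutations | ≤ 0.02 |
| h² CI coverage | 100 studies, 6 pops × 10 families, true h² = 0.5, 200 bootstrap refits | ≥ 0.85 |

The mean Q_ST estimate sits below the generating value (0.27 for a truth
of 0.3 in the recorded run): Q_ST is a ratio of variance estimates and is
biased downward at finite family numbers, a known property of the index
rather than a defect of the fit.

## Known limitations

* The full-sib design cannot separate additive variance from dominance and
  maternal components; `h² = 2·V_w/(V_w + V_res)` is an upper-bound-style
  estimate, as is standard for this design.
* The mean-squares re-estimation in the neutral null assumes an
  approximately balanced design; with strongly unbalanced family numbers
  the chi-square degrees of freedom are approximations.
* The zeroing rule (drop components with nonsignificant boundary LRTs)
  makes downstream Q_ST values discontinuous functions of the data; it is
  applied because the analysis protocol specifies it, and can be disabled.
* GenePop input supports the 2- and 3-digit diploid dialects only; no VCF
  or PLINK, no variable ploidy.
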