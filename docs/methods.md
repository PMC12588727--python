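# Methods

## The outbreeding-response index

The index compares a heterozygous-class trait mean μᵢ against the selfed
null-class mean μ₀ of the same ploidy on a piecewise ratio scale: OR = 1 −
μ₀/μᵢ when μᵢ > μ₀ and OR = μᵢ/μ₀ − 1 when μᵢ < μ₀. It is antisymmetric
(swapping the groups flips the sign), invariant to a common positive
rescaling, and bounded in [−1, 1]; the bounds are attained exactly when one
mean is zero. The two one-sided formulas both tend to 0 at μᵢ = μ₀, so the
tie case returns 0. Negative means are rejected (all 20 catalogue traits are
non-negative), and OR is undefined when both means are zero.

Confidence intervals are percentile bootstrap: each replicate resamples
plants with replacement *independently within each group* — the two groups
are independent samples and the statistic is a function of two group means —
then recomputes the index. BCa or studentized intervals were deliberately not
used; the plain percentile interval is the stated method, and for the small
toy configurations used as oracles the bootstrap distribution can be
enumerated exhaustively and matches the implementation. No multiple-testing
correction is applied across the 20-trait grid; each cell carries its own
interval. Missing trait values are dropped pairwise per trait; plants are
never dropped wholesale.

Per-plant contributions apply the same index with x in place of μᵢ and are
mapped to (0, 1) by (OR + 1)/2, so a plant at the null-class mean scores 0.5.
Contributions are defined only for maximum/reduced plants, and only where the
null-class mean is positive.

## Composite fitness and selection regressions

Pre-dispersive fitness is the product fruit set × seed set; post-dispersive
fitness is survival × germination × leaf number. Both are normalized by the
largest product within the plant's ploidy, so scores live in [0, 1], the best
plant per ploidy scores 1, and the scores are invariant to rescaling the raw
products by a positive constant. A plant missing any component has missing
fitness and drops out of regressions; if every product in a ploidy is zero
the scores are left at zero with a warning rather than divided.

Regressions are ordinary least squares of fitness on the (0, 1)-normalized
contribution, fitted separately per trait × ploidy × comparison × fitness
type, with two-sided t-based p-values and star coding (\*p<0.05 to
\*\*\*\*p<0.0001). Slopes are unstandardized. Because the normalization of
contributions is affine, the slope on the normalized scale is exactly twice
the slope on the raw scale. Degenerate cells — fewer than 3 plants, or a
zero-variance predictor — are flagged, never raised.

## Mixed model and rank test on the OR grid

The unit of analysis is one trait × ploidy OR value (60 rows per
heterozygosity comparison). The mixed model is Gaussian with identity link —
the response is continuous and bounded, and β ± SE / t output is the
reporting convention — fitted by REML (statsmodels MixedLM) with ploidy and
module as treatment-coded fixed effects and a random intercept per trait.
Reference levels are diploid and the alphabetically first module (*fitness*);
they are recorded in the result so any other reference can be re-derived.
Fixed-effect p-values use the t distribution on residual degrees of freedom
(no Satterthwaite approximation is available for this fitter). A fit with the
trait variance on the zero boundary is returned flagged, with fixed effects
then equal to two-factor OLS — a property used as a test oracle.

The Scheirer–Ray–Hare test mid-ranks all responses, computes Type-II sums of
squares on the ranks by least squares (so unbalanced grids are handled), and
refers H = SS/MS_total to chi-square, where MS_total = SS_total/(N−1) is the
variance of the ranks — which automatically carries the tie correction. In a
balanced single-factor layout this H reduces exactly to Kruskal–Wallis, the
independent oracle used in tests. The test is invariant to strictly monotone
transforms of the response. Results are reported both with and without the
interaction term; degrees of freedom come from design-matrix ranks.

## Phenotypic integration

Correlation counts use pairwise-complete observations per unordered trait
pair (at least 4 required), two-sided Pearson tests at α = 0.05 by default,
and no multiplicity correction; a constant trait has undefined correlations
and counts zero. The mean count per trait equals 2 × (significant pairs)/p by
construction. Group differences in per-trait counts use two-sample t-tests
with a compact-letter display built from the maximal cliques of the
"not-significantly-different" graph.

The integration index is the **population** variance of the eigenvalues of
the trait correlation matrix, PINT = (1/p)·Σ(λᵢ − 1)², computed on
complete-case individuals (an eigendecomposition needs one coherent matrix,
whereas counts can use pairwise deletion). Dividing by p (not p − 1) is the
form under which the relative index RelPINT = 100·PINT/(p−1) is internally
consistent with published index pairs at p = 20; this identity is asserted in
the acceptance suite against all nine published group values. Closed forms
used as oracles: identity correlation → 0; two traits with correlation r →
r²; compound symmetry r on p traits → (p−1)r²; rank-one correlation → p−1.
The corrected index subtracts (p−1)/N, the expected eigenvalue variance of a
sample correlation matrix from N independent observations; it is a
documented, configurable convention rather than a validated reproduction of
any published corrected values, which depend on an unpublished N. Bootstrap
CIs resample complete cases (default 10,000 replicates); a degenerate
resample with a constant trait is redrawn. Groups with fewer than p + 1
complete cases are refused (the correlation matrix would be rank-deficient).

## Synthetic cohort generator

The generator emulates the three-ploidy × three-heterozygosity greenhouse
design with default group sizes 257/53/95 (2x), 457/69/238 (4x) and
252/112/89 (6x). Ground truth enters in three ways:

* **OR effects.** A target OR v for (trait, ploidy, comparison) is encoded by
  inverting the index in closed form: the heterozygous generating mean is
  μ₀/(1−v) for v > 0 and μ₀(1+v) for v < 0, so the OR of the generating means
  equals v exactly. Proportion and binary traits reject targets that push the
  mean outside (0, 1).
* **Correlation structure.** Within each group a Gaussian copula imposes a
  requested correlation matrix (validated symmetric PSD with unit diagonal);
  draws pass through Φ and then each trait's marginal quantile function.
  Marginals respect trait support: lognormal for lengths and large totals
  (parameterized by mean and CV, default 0.30), negative binomial for counts
  (dispersion k = 8), beta for proportions (concentration ν = 20), Bernoulli
  for survival. The marginal transforms attenuate Pearson correlations
  somewhat relative to the copula's latent matrix, most strongly for the
  binary trait — recovery tests on injected correlations allow for this.
  Default integration levels are higher for null (within-module r = 0.45)
  than reduced (0.35) than maximum (0.25) groups, emulating the loosening of
  covariation with heterozygosity.
* **Selection.** Optional per-trait slopes link expected pre-dispersive
  fitness to the normalized OR contribution. In that mode fruit set and seed
  set are rebuilt from a latent fitness F = clip(0.60 + Σ slopeₜ·(or_normₜ −
  ½) + ε, 0.02, 1) with independent noise (SD 0.12; independence from the
  predictor traits is required for unbiased slope recovery), split as
  fruit = F^a, seed = F^{1−a} with a jittered around ½ so the product is F
  exactly and both factors stay in (0, 1). The baseline 0.60 puts the
  within-ploidy maximum near 1, so the max-normalization leaves injected
  slopes on their own scale. In this mode the two rebuilt traits' own OR
  targets are not honoured. Default slopes are all zero.

Two populations per ploidy exist as labels only, with no population effect:
all analyses pool within ploidy. Heterozygosity is a class label; no
genotypes or pedigrees are simulated. Identical spec and seed give
byte-identical tables.

What the generator does **not** emulate: measurement error correlated across
traits, family structure within heterozygosity classes, non-monotone
genotype–phenotype maps, or missing data (missingness must be injected by
the caller). Passing recovery tests therefore demonstrate correctness of the
estimators under the stated generative model, not robustness to those
real-data features.

## Pipeline and reproducibility

One global seed spawns fixed per-stage substreams (simulate/OR/selection/
models/integration), so disabling a stage never shifts another stage's
stream; reruns with the same config and seed produce byte-identical CSVs,
and the manifest records a SHA-256 checksum per file. Pipeline defaults are
100,000 bootstrap replicates for OR intervals, 10,000 for integration, and
α = 0.05.

Test and acceptance runs use smaller problem sizes chosen for quick,
deterministic execution: bootstrap replicate counts of 150–5,000 (the
percentile endpoints of the toy oracles are exact already at these sizes),
cohorts of 25–300 plants per group for recovery checks alongside the full
1,622-plant default design, and 20–50 seeds for Monte-Carlo coverage
statements. Coverage thresholds are set from the binomial spread of the
nominal rate at those seed counts (e.g. a 2-SE criterion with true coverage
~95% is asserted at ≥ 88% over 50 seeds).

## Known limitations

* The corrected integration index depends on the complete-case N and is not
  comparable across groups with very different missingness.
* Percentile bootstrap intervals for OR can be mildly anticonservative at
  small group sizes (~50), visible as a slightly >5% flag rate on null
  cells.
* The mixed model's t-based p-values ignore random-effect degrees-of-freedom
  uncertainty; with 60 observations they are adequate for screening, not for
  sharp inference near the threshold.
* The OR index is undefined for traits that can be legitimately negative;
  the catalogue contains none, and the generator never produces any.
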