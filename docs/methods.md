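# Methods

## Model and tests

epiroc treats epistasis detection as a classification question: a pair of
SNPs is interesting when some subset of its joint genotype calls separates
cases from controls better than any call subset of either SNP alone, by a
margin that biased sampling cannot explain.

The *sample prevalence mapping* assigns to each individual the case
fraction among samples carrying the same genotype call (or call pair).
Sorting calls by decreasing prevalence and cumulating control/case counts
(x₀, x₁) yields a concave piecewise-linear ROC curve from (0, 0) to
(t₀, t₁); a fully populated pair table gives 9 segments, a single SNP 3.
Tied prevalences are merged into one segment (exact rational comparison),
which makes the curve unique and concave regardless of tie order; empty
cells are skipped. The pair curve dominates both marginal curves because
its cells refine theirs.

**SS.** For a vertex (x₀, x₁), the probability of sampling at least that
sensitivity (x₁/t₁) and specificity (1 − x₀/t₀) from a population with
π₀ = π₁ is bounded by max_π P(Bin(t₀, π) ≤ x₀) · P(Bin(t₁, π) ≥ x₁). The
SS p-value is the minimum of this bound over the curve's vertices; the
score flt_SS is its −log₁₀. Only vertices with
min(1 − x₀/t₀, x₁/t₁) ≥ `min_ss` (default 0.02) enter the minimum — very
small subsets are unstable at realistic sample sizes. If no vertex
qualifies, p = 1 by convention. The minimum ranges over vertices only:
they are the realisable cumulative count pairs.

**GSS.** The null region H₀ is the smallest convex region of the unit
square containing both single-SNP curves: the concave upper hull (computed
exactly over rationals) of the union of their vertices with (0, 0) and
(1, 1). The inner maximum of the same tail product over (π₀, π₁) ∈ H₀ is
attained on the upper boundary chain, because the objective is increasing
in π₁ and decreasing in π₀; each chain segment is a 1-D maximisation. When
both marginals are diagonal, the chain is the diagonal and GSS equals SS
exactly. Contributing and protective variants restrict the outer minimum
to the vertex subsets with incoming slope ≥ 1 resp. outgoing slope ≤ 1
(slopes in fraction coordinates; vertical = +∞, horizontal = 0; by
concavity every interior vertex lands in at least one subset, slope-1
vertices in both). A pair's headline gain is the larger of the two
directional scores, so it equals the unrestricted minimum and is always
≤ flt_SS of the pair.

**DSS.** flt_DSS = flt_SS(pair) − max(flt_SS(g₁), flt_SS(g₂)), computed on
the pair's complete-case sample subset for all three terms. It may be
slightly negative in edge cases (the vertex exclusion rule applies
per-curve) and is reported as-is.

**Baselines.** Pearson's X² on the 2×V table with the usual expected
counts; p-values from the χ² distribution with V − 1 df (8 for pairs, 2
for singles), with empty columns contributing zero to the statistic while
the df stays nominal — the number of live columns is logged since the
asymptotic p-value is already questionable on sparse 9-cell tables. The
survival function is evaluated from its even-df closed form in log space,
keeping scores finite far beyond X² = 10⁴. The one-sided Fisher exact test
on the cumulated 2×2 table is provided as an SS comparator (their p-values
are numerically close; rank correlation > 0.99 in the test suite), not as
a scan filter.

## Numerical choices

- Binomial tails are evaluated through the regularized incomplete beta
  (P(Bin(t, π) ≤ x) = I₁₋π(t−x, x+1)); values below the double-precision
  floor fall back to direct log-space summation from log-gamma
  coefficients, so nothing underflows for totals through 10⁵.
- Inner maximisations rely on the objective's unimodality in π: a uniform
  257-point grid (per-totals tables of cumulative log-tails built once)
  brackets the maximum, then bounded Brent refinement (xatol 1e-12) inside
  ±2 grid cells. On the GSS chain, each segment is sampled at 33 points and
  the two best segments refined. Agreement with two-stage dense-grid
  oracles is better than 1e-6 in log₁₀ p for totals ≤ 60.
- Edge cases are analytic: x₁ = 0 or x₀ = t₀ give p = 1; π on {0, 1}
  handled exactly.
- The SS inner maximum depends only on (x₀, x₁, t₀, t₁); a per-totals
  memoised kernel caches it, shared across pairs and replicates. Per-pair
  complete-case totals key distinct kernels.
- Outer-minimum ties go to the first vertex in curve order; scans break
  score ties by ascending SNP index pair. Scans are deterministic and a
  dense-data vectorised path produces results identical to the general
  per-pair path.
- Degenerate odds ratios (empty or full subsets) are reported as 0/∞ with
  a flag rather than pseudo-counted.

## Synthetic data

The generator emulates the structure of the standard two-locus benchmark
designs:

- **Null SNPs**: Hardy–Weinberg genotypes at a MAF drawn per SNP (default
  uniform on [0.05, 0.5]), independent of phenotype.
- **Pure-epistasis pairs**: a family pattern (xor, threshold, dominant) is
  centred to zero HWE mean, normalised, and its outer product added to a
  constant base penetrance (default 0.25) scaled by `effect_scale` (the
  maximum penetrance deviation). Both HWE-weighted marginal penetrances
  are then constant *exactly*, so the planted pair carries no univariate
  association at the population level; infeasible scales raise an error
  naming the feasible range. Case/control genotypes are drawn from the
  exact conditional cell distributions given status (equivalent in
  distribution to prospective rejection sampling, at deterministic cost);
  prevalence is implicit in the table.
- **Main-effect confounders**: one SNP with genotype relative risks over a
  base penetrance (default 0.1), sampled retrospectively; pairing it with
  null SNPs reproduces the χ² hub/banding phenomenon.

What the generator does **not** model: linkage disequilibrium, population
stratification, genotyping error, multiple or partially overlapping
signals. Passing tests therefore demonstrate correctness of the statistics
and the machinery on idealised data, not robustness to real-data
artefacts.

The power harness plants one pair per replicate among null SNPs, scans
with DSS and χ², and calls a detection when the score passes a Bonferroni
level (1/C(m, 2) by default, or an explicit external threshold).
Per-replicate seeds are `seed + index`.

## Problem sizes used by the default test run

Chosen so the full suite completes comfortably on a single core:
pipeline-recovery uses 100 replicates of 102 SNPs at 800/800 samples with
the strong xor model (maf 0.5, scale 0.2); the power grid is xor at maf
{0.2, 0.4} × 200/800 cases (= controls), scale 0.15, 100 replicates of 50
SNPs against the fixed external benchmark threshold 2×10⁻⁶; ordering and
calibration suites use 200 SNPs at 60/60 and 10,000 SNPs at 500/500
respectively.

## Known limitations

- The SS/DSS scores are *filter scores*, calibrated for ranking and for
  extreme genome-wide thresholds. At moderate levels the null distribution
  of p_SS is anticonservative: the outer minimum runs over vertices of the
  data-selected prevalence ordering, so P(p_SS ≤ 0.05) on null SNPs is
  well above 0.05 even though each fixed-subset bound is exact. At the
  Bonferroni levels the scans actually use (10⁻⁶ and beyond) the observed
  false-positive rates are near zero. Treat flt_SS/flt_DSS as ranking
  scores, and the exact GSS stage as the confirmatory test.
- The χ² 8-df p-value on sparse 9-cell tables inherits the usual
  large-sample caveats.
- No covariates, no dosages, no 3-way scans; PLINK 1 formats only.
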