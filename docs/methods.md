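# Methods

## Scope

`hicnb` calls statistically significant 3D chromatin interactions in
Hi-C/HiChIP contact matrices against a negative-binomial GLM background,
tests for differential interactions between two replicated conditions, and
provides TAD and A/B-compartment callers. Everything is testable on
synthetic data generated by `hicnb.simulate`, which draws counts from the
same model the fitter assumes.

## Background model

For an intra-chromosomal bin pair (i, j) at genomic distance d with count
y_ij, the null model is

    y_ij ~ NB(mu_ij, alpha),        Var = mu + alpha * mu^2
    log mu_ij = beta0 + sum_k beta_k B_k(d)
                + beta_gc x_gc + beta_map x_map + beta_len x_len

- **Distance spline.** B_k are cubic B-spline basis functions of *linear*
  genomic distance with six degrees of freedom and three inner knots at the
  25/50/75% quantiles of the fitted pairs' distances (linear interpolation
  between order statistics; ties deduplicated with a log-spaced fallback).
  Six columns are the full clamped 7-function basis minus its first
  function, whose span the GLM intercept absorbs; the full basis satisfies
  the partition of unity and is verified against an independent Cox-de Boor
  recursion. A power-decay alternative replaces the spline with a single
  centered log(d) covariate.
- **Covariates.** Per-bin GC content, mappability and effective bin size
  (fraction of the bin within ±500 bp of a restriction cut site; GC uses a
  200 bp wider window) are averaged over the two anchors and standardized
  per chromosome (mean/SD recorded in the fit JSON). Pairs with a flagged
  anchor (no cut site, missing track data) are excluded from fitting and
  reported with sentinel NaNs, never p = 1.
- **Distance definition.** d = (bin_j − bin_i) × binsize for uniform bins
  (exact per diagonal), midpoint distance for restriction-fragment bins.
  Defaults: d_min = binsize (the diagonal is dominated by self-ligation
  artifacts), d_max = 2 Mb.

## Two-step fit

Per chromosome, independently:

1. Fit the NB GLM on a distance-stratified subsample (25% of pairs, at
   least 100,000, all if fewer; systematic sampling along the distance
   ordering with a seeded jitter). Beta is updated by IRLS at fixed
   dispersion, alpha by bounded univariate likelihood maximization at fixed
   mean, alternating until the relative deviance change is below 1e-8 (max
   25 rounds). Dispersions below 1e-5 trigger a Poisson fallback.
2. Flag every pair whose count exceeds the 97.5% quantile of its fitted
   null NB — candidate non-random contacts — and refit without them. The
   default refit maximizes the **right-truncated** NB likelihood,
   conditioning each retained pair on its count not exceeding its own trim
   threshold. Ignoring the truncation (available as `trim_refit="plain"`)
   underestimates the mean by ~3% and the dispersion by ~20% on null data,
   visibly inflating small P-values; the truncated refit recovers the
   generating parameters essentially exactly. An error is raised if more
   than half of all pairs are trimmed (misspecification signal).

The expected trimmed fraction is *below* 2.5% by construction: for a
discrete NB, P(Y > ppf(0.975)) ≤ 0.025 with a deficit that grows as the
mean shrinks. On the default synthetic world it is ~2.1–2.2%.

Model families: `nb` (default), `ztnb` (zero-truncated NB maximizing the
truncated likelihood on positive pairs, with analytic gradients), and
`hurdle` (ridge-stabilized logistic zero part plus the ZTNB positive
part). Dispersion is constant per chromosome by default; the
distance-dependent option estimates alpha per equal-occupancy distance
stratum (strata under 200 pairs merged leftward) with the fitted means held
fixed, then isotonically smooths log alpha against log d (direction chosen
by the data) and interpolates.

## Significance

The P-value of a pair is the upper-tail survival probability of its fitted
null, 1 − F(y) = P(Y > y), computed through scipy's regularized
incomplete-beta survival function and verified against brute-force pmf
summation to 1e-12. Two consequences of this strict-inequality convention
on discrete counts are deliberate and documented:

- p = 1 is unattainable and a zero count can never be significant;
- the null distribution of p is *not* sub-uniform: P(p ≤ t) = S(k_t − 1),
  where k_t is the smallest count with S(k) ≤ t, which exceeds t by up to
  the null pmf mass at k_t − 1. On a deep 5 kb Hi-C world this excess is
  ~0.3% at t = 1% and ~2% at t = 10%. The conservative alternative would
  be P(Y ≥ y); the strict convention is retained as the method's defining
  formula, and the test suite asserts the exact discrete bound
  (t + fitted atom mass) rather than plain uniformity.

Benjamini-Hochberg correction is genome-wide across all tested pairs by
default (per-chromosome scope by flag). O/E (y/mu) and NB Z-scores
((y − mu)/sqrt(mu + alpha mu²)) are exported for visualization and for the
domain callers.

## Differential testing

The testing universe is the union atlas of pairs significant at FDR < 0.1
in at least one condition, called on pooled replicate counts. Size factors
are per sample and per genomic distance: the raw factor ŝ_d is the median
count at distance d over pairs with a nonzero count in at least one sample
(the all-pairs median vanishes on sparse distant diagonals; a still-zero
stratum inherits the sample's nearest valid shorter-distance factor). The
factor actually divided out is ŝ_d centered by the cross-sample median at
that distance, which keeps normalized counts on the raw count scale — the
NB mean-variance relationship needs the magnitude — while equalizing
per-distance medians across samples. An engine dividing by raw medians
flattens every distance stratum to O(1) counts, which an NB family (var ≥
mean) cannot represent; we measured a type-I rate of 0 for that variant.

The test itself is a self-contained vectorized shrinkage NB Wald test on
the normalized counts (continuous NB quasi-likelihood via `gammaln`):

1. per-pair GLM (intercept + condition; IRLS reduces to 2×2 solves),
2. per-pair Cox-Reid-adjusted dispersion MLE by vectorized golden-section
   search on log alpha in [1e-8, 30],
3. a parametric trend alpha(m) = a0 + a1/m fit by reweighted gamma-style
   least squares (weights 1/pred²); lower-boundary dispersion estimates are
   *included*, floored at the boundary — excluding them biases the trend
   upward exactly in low-dispersion regimes and we measured the type-I rate
   dropping from 0.045 to 0.025 when they are dropped,
4. empirical-Bayes shrinkage of log-dispersions toward the trend, prior
   variance = max(MAD² of interior residuals − trigamma((n−p)/2), 0.25),
5. Wald test of the condition coefficient (normal reference), BH over the
   atlas. Swapping condition labels negates every log2FC exactly; results
   are invariant to replicate order.

Rescaling any single sample by c rescales its ŝ_d by c; Wald statistics
are unchanged for every stratum where the sample's factor sits at or above
the cross-sample median and move by at most ~0.1 elsewhere (the rank shift
moves the center slightly). Exact invariance is incompatible with any
calibrated engine: valid inference must respond to a sample's information
content.

## TAD caller

Input is a dense symmetric normalized matrix (the package's O/E or
Z-scores, or an externally normalized matrix). The caller first divides
each diagonal by its mean — a no-op on properly O/E-normalized input —
because the boundary test compares cross-boundary entries (larger |i−j|)
with within-block entries (smaller |i−j|) and any residual distance decay
would make it fire everywhere; this also makes the caller exactly
scale-invariant. Then:

1. boundary signal: for each inter-bin boundary, the mean of the w×w
   submatrix connecting the w bins on either side (w = 10 by default),
   edge-truncated;
2. candidates: local minima of the signal (plateau-aware);
3. filtering: a candidate is kept when the one-sided Mann-Whitney test
   finds cross-block values significantly lower than flanking within-block
   values at p < 0.05.

Zero-coverage runs are split out and labeled `gap`; retained boundaries
partition the rest into `domain` intervals that tile the chromosome.

## Compartment caller

At coarse resolution (100 kb default), the Pearson correlation matrix of
the O/E matrix is column-centered and its leading eigenvector taken
(`numpy.linalg.eigh`). Bins with zero or constant signal are excluded and
left unlabeled. The eigenvector sign is arbitrary; when per-bin GC is
supplied the sign is oriented so the GC-richer group is "A", with ties
broken toward labeling the first bin's group B. A degenerate (constant)
matrix raises instead of emitting unstable labels.

## Synthetic world

The default generator emulates one chromosome of a deeply sequenced,
merged-replicate Hi-C library at 5 kb resolution: 2,000 bins, pairs up to
2 Mb (~720k), first-diagonal mean ~300 decaying as ~d^-0.75 to a few
counts at 2 Mb, constant alpha = 0.15, and covariate effects of 0.30 /
0.25 / 0.20 per SD of GC / mappability / effective size. The spline-decay
coefficients are obtained by projecting the target power law onto the
actual spline basis, so the truth lies exactly in the fitted model family
and parameter recovery is well defined. Replicate draws use a separate
dispersion, alpha_rep = 0.01 (BCV 10%): replicate-to-replicate variation is
Poisson-dominated technical noise, whereas the background alpha absorbs
genomic structure that is shared across replicates and cancels in
between-replicate comparisons. Features are beta-distributed in [0, 1];
planted loops multiply the mean of chosen pairs (uniformly selected unless
a mean floor is requested) by a fold factor; TAD matrices are
block-diagonal and compartment matrices checkerboard, both with power-law
decay and NB noise.

What a green test does **not** establish: the generator has no ligation
noise, no copy-number or translocation artifacts, no inter-chromosomal
contacts, no ChIP enrichment structure for HiChIP, and its covariates are
independent across bins. Real-data biases outside the model family (e.g.
unmodeled ChIP signal) are not represented.

## Numerical choices and edge cases

- Dispersion parameterization var = mu + alpha mu² everywhere, alpha ≥ 0
  via log-parameterization; searches bounded in [1e-8, 100] (fit) or
  [1e-8, 30] (per-pair differential).
- Linear predictors clipped at ±30 before exponentiation.
- Out-of-support distances are clamped to the training boundary knots at
  prediction time.
- All-zero responses, rank-deficient designs, fewer than 10 observations
  per parameter, >50% trimming, empty atlases and degenerate matrices
  raise informative errors rather than returning numbers.
- Every stochastic routine takes a mandatory seed; fits serialize to JSON
  with enough state (coefficients, knots, scalers, options, seed) to
  reproduce predictions bit-exactly.

## Known limitations

- Binary `.hic`/`.cool` adapters are not included (no reader available in
  the supported dependency set); HiC-Pro `.matrix`/`_abs.bed`,
  allValidPairs and a generic bin-pair TSV are. Mappability is consumed as
  bedGraph-like text, not bigWig.
- Raw counts only; externally balanced (ICE/KR) matrices are accepted by
  the TAD caller but never produced or consumed by the background model.
- Two-condition differential designs only; no LFC shrinkage, no outlier
  replacement, no independent filtering.
- The strict survival P-value convention is mildly anti-conservative on
  discrete counts (quantified above); users needing guaranteed FDR control
  at small counts should threshold more stringently.
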