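# Methods

This note documents the models, conventions and design choices behind
`microqtl`, in the spirit of a statistical-software methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design and the synthetic generator

The package targets an F2 intercross between two inbred mouse strains
(B6 × FVB), with individuals randomized to two diets (American /
ketogenic, half each) and both sexes, genotyped at ~1,700 informative
autosomal markers, and phenotyped by 16S ASV counts. Since such data
are rarely redistributable, `microqtl.simulate` generates complete
studies with recorded ground truth:

* **Map** — 19 autosomes (the X is excluded: an F2 from a
  unidirectional cross complicates X dosage and the analysis targets
  autosomal loci); marker positions are sorted uniforms per chromosome,
  default 88/chromosome × 19 ≈ 1,670 markers over 90 cM. Physical
  positions use a fixed linear 2 Mb/cM conversion; intervals are
  reported in Mb.
* **Genotypes** — each individual is the sum of two independent
  gametes; within a gamete the first allele is equiprobable and each
  inter-marker interval switches with Haldane's recombination fraction
  r = (1 − e^(−2d/100))/2 (no crossover interference — standard for F2
  simulation and closed-form testable). This yields 1:2:1 segregation
  at every marker. Codes: 0 = B6/B6, 1 = het, 2 = FVB/FVB, −1 missing.
* **Covariates** — diet assignment is balanced deterministically
  (round(n·fraction) American), sex is Bernoulli(½).
* **Counts** — per taxon, log mean = baseline + diet·1[keto] +
  sex·1[male] + a·g + d·1[het] (+ interaction term routed to the
  ketogenic or male stratum), multiplied by a lognormal per-sample
  library factor (default mean 26,000 reads, σ = 0.3 on the log scale,
  so rarefaction genuinely subsamples), with negative-binomial noise
  (size = dispersion) and an independent point mass of extra zeros.
  Zero inflation is covariate-independent by default; the paperless
  truth here is deliberately simple — a point mass at zero — because no
  canonical generative model exists for technical zeros.
* **Default effect layout** — baselines follow a lognormal
  rank-abundance profile normalized to relative abundances; 60% of taxa
  receive a diet main effect ~N(0, 1) on the log scale (diet is the
  dominant driver, as in real diet-contrast studies); small sex
  effects ~N(0, 0.15); three marginal, two diet-interaction and one
  sex-interaction QTL are planted on the most abundant taxa so the
  traits survive the core-microbiota filter.

**What the generator does not emulate:** compositional closure imposed
by sequencing (taxa are drawn independently given the library factor),
phylogenetically correlated abundances (the tree is independent of the
count model), segregation distortion, X/Y/mito inheritance, and
covariate-dependent zero inflation (available via config but off by
default). Passing recovery tests therefore demonstrate correctness of
the statistical machinery under a realistic but idealized null — not
robustness to every failure mode of real 16S data.

**Planted-effect calibration.** The recovery experiments use a marginal
QTL of additive log-effect log(1.3) per FVB allele on an abundant taxon
(relative abundance 0.01, dispersion 2, zero inflation 0.05), chosen
once so that the marker explains ≈5% of the variance of the
quantile-normalized trait at n = 469 (the acceptance script reports the
realized percentage). Diet-interaction recovery plants additive
+log(1.8) with interaction −log(1.8), i.e. a genotype slope confined to
the American stratum, so the stratum-specific allele effects have a
defined sign.

## Trait construction

* **Rarefaction** — single subsample without replacement (multivariate
  hypergeometric) to depth 4,500; samples below depth are dropped and
  reported, not padded. A 4,499-read sample is dropped.
* **α-diversity** — Shannon in log base 2 (bits; the QIIME2 convention,
  switchable) and observed species, computed on the unfiltered rarefied
  table.
* **β-diversity** — Bray–Curtis, binary Jaccard, unweighted UniFrac
  and weighted UniFrac (non-normalized by default, matching the plain
  QIIME2 metric; the normalized variant divides by Σ l_b(A_b+B_b) and
  sits behind a flag). Pairs of all-zero samples are at distance 0 by
  convention; weighted UniFrac refuses zero-total samples. Distances
  are computed via scikit-bio; the test suite checks them against an
  independent brute-force per-pair branch tally to 1e-12.
* **PCoA** — Gower double-centering and symmetric eigendecomposition.
  Negative eigenvalues are retained in the reported spectrum but
  excluded from coordinates and from the proportion-explained
  denominator; no Cailliez/Lingoes correction. Axis signs are fixed by
  forcing each axis's largest-magnitude loading positive, for
  reproducibility (scans are invariant to trait sign anyway).
* **Filters** — the prevalence filter keeps ASVs seen *more than* 5
  times in at least 5% of samples (ceil on the sample count); the core
  measurable microbiota keeps ASVs with nonzero post-rarefaction counts
  in at least 20% of individuals, boundary inclusive. Presence is
  evaluated post-rarefaction (the pre/post choice is not canonical; the
  post-rarefaction reading keeps the CMM consistent with the table the
  scans actually use).
* **Quantile normalization** — classic reference-distribution
  semantics: sort each column, average across columns at each rank,
  assign by rank. Ties within a column receive the mean of the
  reference values spanning their rank range (note: rank-averaging
  implementations interpolate the reference at the mean rank instead;
  the two differ only for ties spanning >2 ranks over a locally
  non-linear reference). Missing values are excluded from ranking and
  preserved; incomplete columns are aligned to the n-point reference by
  linear interpolation on the rank scale. Only CMM abundance columns
  are normalized — diversity and metabolic traits enter scans
  untransformed.

## Genome scans

* **LOD** — `(n/2)·log10(RSS₀/RSS₁)`, clamped at 0, with the marker as
  a 2-df factor so additive and dominance effects are both captured
  (the reported allele effects are separate het and hom contrasts
  relative to B6/B6). The RSS form is pinned against the algebraic
  F-statistic identity `LOD = (n/2)·log10(1 + F·df₁/df₂)` to 1e-10 in
  the tests. Rank-deficient designs (an absent genotype class) are fit
  on the reduced column space; markers with too few usable rows are
  skipped with a missing LOD. Missing genotypes are handled by
  per-marker case deletion; scans run at markers only (no
  pseudomarkers).
* **Permutations** — the trait vector is shuffled across individuals
  with covariates and genotypes fixed, for all three models. For the
  interaction models this is a global-null (conservative) scheme since
  the permutation also destroys the marker main effect; a stratified
  mode (within diet or sex) is available via `stratify_by`. Per-trait
  thresholds are empirical (1−α) quantiles of the per-permutation
  genome-wide max LOD; the class threshold is the mean over the class.
  Complete columns sharing identical sorted values (quantile-normalized
  traits) provably share their permutation null, so one batch serves
  the group — asserted exact in the tests. Default 1,000 permutations
  (10,000 for production thresholds).
* **Calling** — at most one peak per chromosome per trait per model
  (multi-QTL models are out of scope), strict exceedance of the 5%
  class threshold, flagged highly significant above the 1% threshold.
  Support intervals walk outward to the first markers below
  peak−1.5 LOD, including those flanking markers; chromosome ends cap
  the interval.
* **Variance partition** — sequential (type-I) ANOVA with fixed order
  sex, diet, sex:diet, marker (marginal) or sex, diet, marker,
  interaction; a term's share is 100·SS(term)/SST with SST the centered
  total sum of squares, p-values from term F tests against the
  full-model residual. The alternative reading R²(alt)−R²(null) is
  available from the per-marker RSS output.
* **Colocalization** — closed-interval overlap on the same chromosome
  (touching endpoints count), groups as connected components, interval
  containment flagged per ordered pair.

## Path models

The estimator is deliberately equation-wise least squares on
standardized four-quantile ordinal scores, not diagonally weighted
least squares over polychoric correlations: the inferential surface of
interest is the set of standardized path coefficients and their
significance in a recursive (acyclic) system, which this reproduces
without a latent-variable engine. Consequences: coefficients are
attenuated relative to the latent scale (binning acts as measurement
error), and a small direct effect can leak past binned mediators —
which is why structure-recovery tests allow one spurious edge.
Covariance paths are residual correlations with Fisher-z p-values.
Backward refinement is deterministic: remove the worst p ≥ α path
(ties: smaller |coefficient|, then lexicographic edge), refit, stop
when all retained paths are significant; path-less variables drop out.
Genotype enters as additive FVB dose 0/1/2; genotype×diet products are
formed before fitting for diet-specific structures.

## Numerical choices

* Orthonormal-basis RSS computation (SVD with tolerance 1e-9·√n on the
  relative singular value) everywhere a nested model is compared;
  identical code path for single-trait and vectorized multi-trait
  scans, cross-checked in tests.
* Empirical quantiles: numpy's default (type-7, linear interpolation)
  both for permutation thresholds and ordinal collapse; ordinal
  boundary ties go to the lower bin.
* Seeds thread through every stochastic operation via
  `numpy.random.SeedSequence` spawning; all derived seeds are < 2^31;
  identical seed ⇒ byte-identical serialized study bundles and
  identical run-manifest checksums.

## Problem sizes used in the shipped experiments

The test suite and acceptance script run scaled versions of the full
design, chosen to exercise every code path at desk scale: calibration
uses 100–200 null traits × 200 markers × n = 300 × 500–1,000
permutations; recovery uses n = 469 × 380 markers (19 × 20) × 300
permutations over 20–50 seeds; the end-to-end pipeline run uses 469
individuals, 380 markers, 120 ASVs and 300 permutations. Production
analyses would raise markers to the full map and permutations to
10,000; nothing in the implementation depends on the scaled sizes.

## Known limitations

Single-QTL-per-chromosome calling; no interval mapping, epistasis or
kinship correction (appropriate for an F2 with unrelated founders, but
not for advanced intercross or outbred designs); compositionality of
counts is acknowledged but not modeled (no CLR/ILR transforms —
quantile normalization plus permutation is the supported route); the
path-model estimator is not DWLS and its coefficients are attenuated;
UniFrac variants beyond the two implemented (generalized,
variance-adjusted, Faith's PD) are out of scope.
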