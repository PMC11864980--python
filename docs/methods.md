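# Methods

This note documents the statistical model behind each pipeline stage, the
parameters that matter, the design of the synthetic cohort generator, and
the numerical conventions that a careful reader would otherwise have to
reverse-engineer from the code.

## Region copy number and deletion calling

Segment tables give, per model, non-overlapping intervals with a linear
relative copy ratio (1.0 ≈ diploid-normal). The region summary is the
overlap-length-weighted mean of the ratios of segments intersecting the
region, computed **on the linear scale**, then transformed as
`log2(ratio + 1)`; averaging before the log matters because the log is
concave and segment ratios near zero would otherwise dominate. The
weighted mean is normalised by *covered* length rather than region length:
a segmentation gap is treated as absence of evidence, not as copy number
zero. Models whose segments cover less than `coverage_floor` (default 0.5)
of the region are reported `missing` rather than called. The deletion call
is a strict inequality, `value < threshold`, with 0.4 as the default
threshold; a sweep over {0.2, 0.3, 0.4, 0.5, 0.6} (step 0.1 — the
continuum between 0.2 and 0.6 has no canonical grid) guards against
cutoff artefacts. Coordinates are 0-based half-open throughout; the
9p21.3 literal (chr9:19,900,000–25,600,000) is ingested as written.

## Differential-dependency screen

Gene-effect scores are on the conventional CRISPR screen scale: 0 at the
negative-control median, −1 at the pan-essential median; more negative
means more essential. For each gene, biomarker-positive and -negative
models are compared with the classical **pooled-variance** (equal-variance)
two-sample Student's t-test, left-tailed, on complete cases for that gene.
Welch's correction is deliberately not applied — the screen mirrors the
named classical test — but the primitive accepts either tail, and the
one-tailed p always comes from the signed statistic's own tail, never from
halving a two-sided p. Benjamini–Hochberg adjustment runs across all
tested genes of one screen (and separately within each threshold of a
sweep). Genes with fewer than `min_group_size` (default 5) complete cases
in either group, or with zero pooled variance, are emitted as untested
rows with null statistics so that output row count always equals input
gene count. There is no canonical floor for the group size; 5 is the
smallest group for which the pooled t has any resolution, and real
screens operate far above it.

## Biomarker association

Omics sources are concatenated into one models × features matrix with
`<type>:<name>` namespacing; features measured in fewer than ten models
are dropped before testing (the count is logged). Associations are
pairwise-complete Pearson correlations against the target gene's
dependency profile, restricted by default to region-intact models (in the
motivating analysis the deleted models would otherwise dominate every
correlated feature). P-values are two-sided — the conservative choice,
since the direction of a novel biomarker is not known in advance — with BH
across tested features; constant or under-observed features are excluded
from the BH denominator. The complex-minimum protein feature takes the
per-model minimum across the SKI-complex members and is missing whenever
any member is unmeasured; its motivation is that complex function tracks
the limiting subunit, and the minimum of several noisy readouts of a
shared latent is also a lower-variance estimate of that latent.

The composite biomarker call is `region value < 0.4 OR weighted repeat
length ≤ 9`. With an 11-unit reference tract, length ≤ 9 is the same rule
as "at least two repeat-unit deletions". Both thresholds are configurable.

## Microsatellite repeat lengths and MSI status

Per-site read histograms are summarised by their weighted mean length —
scale-invariant in read depth, missing when a site has no reads. The
on-disk dialect is a deliberately simple two-line record (header:
chromosome, span, repeat unit, reference length; counts:
`length:read_count` pairs, `-` for zero reads); real callers' formats vary
by version, so the reader is kept small and replaceable. The MSI score is
a documented proxy for the upstream per-site machine-learning classifier
of MSIsensor-style tools (out of scope here): a site counts as modified
when its weighted length deviates from the catalogue reference by at
least 0.5 repeat units, the score is the percentage of evaluated sites
modified, and MSI-H means score strictly above 20. Site–dependency
association uses raw weighted lengths (not reference-normalised) and is
restricted by default to MSI-H models, where repeat lengths actually
vary.

## Modifier screen

Counts are scaled to reads per million per sample; log2 fold change is
taken against the plasmid-DNA reference with pseudocount 1 (configurable,
≥ 1 so LFCs stay finite). ΔLFC is the per-guide difference between a
sensitized arm and the control arm, matched on (replicate, timepoint);
the analysis timepoint is explicit configuration, defaulting to the
latest day present in the sample sheet. The per-gene test is a left-tailed
Wilcoxon rank-sum of the gene's ΔLFC observations (unit: guide ×
replicate × sensitized arm) against all other guides' observations.

Gene effects are estimated as mean guide-level LFC per target and then
anchored so the negative-control median is exactly 0 and the
positive-control median exactly −1. Full count-model deconvolution
(Chronos-style) is intentionally out of scope — the rank-sum confirmation
analysis does not depend on it — and the mean-LFC estimator is labelled as
the simple substitute it is. The anchoring median is the **lower middle
order statistic**, i.e. an actually observed effect: an interpolated
midpoint median would reproduce the anchors only to rounding error,
whereas an observed anchor maps to exactly 0.0 and the positive anchor to
exactly −1.0 in IEEE arithmetic. Anchoring requires the positive-control
median to lie below the negative-control median; anything else indicates
mislabelled control classes and raises.

## Synthetic cohort generator

The generator emulates the statistical structure in which such a
discovery is possible, at desk scale, with all randomness drawn from one
seeded `numpy` generator (same config + seed ⇒ byte-identical files).
Defaults: 500 models, 2,000 genes, 500 microsatellite sites — sized so the
full validation suite runs in minutes on one CPU.

* **Copy number.** 10% of models are deleted: their 9p21.3-spanning
  segment draws a ratio from Uniform(0, 0.15) (region value ≤ 0.20). All
  other segments draw Normal(1, 0.1) clipped below at 0.5 (region value
  ≥ 0.58). The clip is a deliberate margin: it guarantees the planted
  deleted set is exactly recoverable at the 0.4 call, which is what makes
  exact-set assertions meaningful. Real cohorts have borderline models;
  the generator does not emulate them.
* **Dependency.** Gene effect = μ_g + δ·1[biomarker] + Normal(0, 0.2),
  with μ_g = −1 for a 10% essential fraction and 0 otherwise. Three genes
  are planted at δ = −0.5: one on the deletion biomarker, one on the
  causal-site contraction, one on their OR. Keeping the deletion-linked
  gene separate keeps its group-difference estimate of δ uncontaminated
  (the OR-linked gene's "negative" group contains contracted models);
  the OR-linked gene mirrors the dual-biomarker structure of the
  motivating dependency.
* **Microsatellites.** 15% of models are MSI-H. Read depth per site is
  Poisson(30). Unmodified sites place reads symmetrically around the
  reference length (one-tenth of reads one unit either side), so their
  weighted mean equals the reference exactly. Each MSI-H model contracts
  exactly half of its sites by k ~ min(Geometric(0.5), 5) ≥ 1 units; the
  causal site (an 11-thymidine tract) is always contracted in MSI-H
  models, with the same k distribution, so roughly half of MSI-H models
  cross the ≤ 9 biomarker rule (k ≥ 2) and the planted δ applies exactly
  to those. Guaranteed ≥ 1-unit contractions against an exact-reference
  background make the |Δ| ≥ 0.5 modified-site proxy and the score > 20
  MSI-H call separate the planted classes with certainty; the
  within-MSI-H variation in k is what makes the causal site
  identifiable by correlation.
* **Protein.** The three SKI-complex members share a latent
  (−1 in biomarker-positive models, Normal(0, 0.3) otherwise-spread) plus
  member noise Normal(0, 0.8); 5% of entries are missing. Member noise
  deliberately dominates the latent: that is the regime in which the
  complex-minimum feature out-predicts each single member, the property
  the generator exists to exhibit (the minimum of three noisy copies has
  ≈ 0.56× the noise variance of one copy).
* **Modifier screen.** 200 guides (40 genes × 4 guides + 20 negative
  + 20 pan-essential controls), three arms (control + two sensitized),
  three replicates, days 5/9/13, lognormal plasmid pool, negative-binomial
  counts (dispersion 0.1) around `share × 2^(fitness × day)`. The planted
  modifier is lethal (−0.15 LFC/day) only in sensitized arms;
  pan-essential controls are lethal everywhere.

What passing tests on this cohort do **not** show: robustness to
segmentation noise near the deletion threshold, to MSI scores near 20, to
stutter asymmetric around the mode, to lineage structure or batch
effects, or to guide-efficacy variation. The generator is a correctness
harness, not a realism benchmark.

## Numerical conventions and edge cases

* Missing values: listwise deletion within each group for two-sample
  tests, pairwise for correlations; missing biomarker measurements count
  as negative in the composite OR call.
* Rank-sum test: midranks for ties, plain normal approximation, no
  tie-variance or continuity correction.
* Correlations need ≥ 3 complete pairs and non-constant vectors;
  constancy is decided on the raw values (a centred sum-of-squares can
  carry rounding residue for a constant column).
* BH adjustment: step-up, order-preserving, q ≥ p elementwise; untested
  items never enter the denominator.
* Determinism: generator output depends only on (config, seed); pipeline
  output TSVs carry a provenance header with the package version, a hash
  of the analysis configuration (output paths excluded) and the seed.

## Known limitations

The gene-effect estimator for the modifier screen is mean LFC, not a
count-model fit; expression/protein matrices in the generator have no
covariance structure beyond the planted signals; the MSI proxy score is
threshold-based and will disagree with classifier-based callers near the
decision boundary; and the pipeline performs no lineage or covariate
adjustment — associations are marginal by design.
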