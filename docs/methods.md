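# Methods

This note records the models, conventions, and design choices behind
`betaci`, in the spirit of a statistical-software methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model

The pipeline's currency is the taxa × samples integer count table (classic
OTU-table orientation).  Readers accept tab-separated tables in either
orientation and BIOM v1 JSON; identifiers are opaque strings and taxonomy is
never parsed from names — resolution structure is supplied explicitly as a
`TaxonomyHierarchy`, an ordered list of levels (finest → coarsest) with a
cluster label per taxon per level.  Refinement consistency (taxa merged at a
finer level stay merged at every coarser one) is validated at construction
and violations are hard errors: a silently inconsistent hierarchy would
corrupt the resolution axis of every sweep that uses it.  Collapsing to a
level sums member rows and conserves per-sample totals exactly.

## Normalization

**Cumulative sum scaling (CSS).**  For sample *j*, the scaling factor is the
sum of counts `c_ij ≤ q_j`, where `q_j` is a quantile of the sample's
*positive* counts; values are `c_ij / s_j × scale_constant`.  The quantile
is fixed (default p = 0.5) and configurable; the adaptive quantile-selection
of the original CSS proposal is deliberately out of scope — a fixed median
is the documented default behavior and gives bit-exact testability.
Quantiles use the linear-interpolation order-statistic definition (numpy's
default) so one convention holds everywhere.  `scale_constant` defaults to
1000; only relative abundances matter to the dissimilarities used.  CSS
preserves the zero pattern, so binary Jaccard is identical before and after
CSS — asserted in the tests.

**Rarefaction.**  Each sample is subsampled *without* replacement to the
requested depth (one multivariate hypergeometric draw per sample), so
rarefied column sums equal the depth exactly and no rarefied count exceeds
its original.  Samples shallower than the depth are dropped with a logged
warning rather than upsampled — padding with replacement would fabricate
reads.  A sweep cell whose groups are exhausted by the depth filter is
recorded as failed, not fatal.

## Dissimilarity

Bray-Curtis `d_ij = Σ|x_ki − x_kj| / Σ(x_ki + x_kj)` and binary Jaccard
`d = 1 − |A∩B|/|A∪B|` (presence strictly `> 0`), both bounded in [0, 1],
computed with scipy's pairwise-distance kernels.  The metric functions are
pure: they operate on whatever table they are given (raw, rarefied, or
CSS-normalized); the sweep engine owns the pairing of normalization with
analysis (CSS for effort-only sweeps, raw rarefied counts for depth sweeps,
raw counts for the drift experiment).

## Effect sizes and permutation inference

ANOSIM and one-way PERMANOVA are implemented from their definitions (see
README for the formulas); scikit-bio's implementations are used in the test
suite as an independent oracle, never as the computation path.  Conventions:

- Ties get average ranks.  This is what makes ANOSIM well defined under
  bootstrap resampling *with replacement*, where duplicated samples create
  exact ties at distance 0.
- Permutations are drawn uniformly with replacement from the permutation
  group (distinctness not enforced), and the p-value uses the +1 correction,
  so `p ∈ (0, 1]` and `p` can never be 0.  With PERMANOVA the permuted
  statistic is pseudo-F; because SS_T is permutation-invariant, F and R²
  order permutations identically.
- The "greater or equal" comparison uses a 1e-12 tolerance to avoid
  float-ordering artifacts across platforms.
- Degenerate inputs: SS_T = 0 (all samples identical) raises a dedicated
  error; SS_W = 0 with separation yields the sentinel pseudo-F = +inf and
  R² = 1.
- One-way designs only; no dispersion (PERMDISP) test, no post-hoc pairwise
  comparisons, no blocked permutations.

Under exchangeable labels the exact permutation distribution satisfies
`E[R] = 0` and `E[R²] = (a−1)/(N−1)`; both identities are verified by
exhaustive enumeration in the tests, and univariate Euclidean pseudo-F is
checked against the classic one-way ANOVA F.

## The bootstrap CI sweep

One grid cell = (effort, depth, resolution, metric, test).  Each of the
`n_boot` (default 1000) replicates runs, in order:

1. collapse the table to the resolution level (a property of the table, so
   it must come first);
2. rarefy every surviving sample to the depth with a replicate-specific
   stream (each replicate re-rarefies, then subsamples);
3. CSS-normalize if configured (default: effort-only sweeps yes, depth
   sweeps no; re-normalization after rarefaction is a switch, default off);
4. draw `effort` samples per group uniformly **with replacement**,
   duplicates kept as distinct sampling units;
5. compute the distance matrix and the statistic (ANOSIM R or PERMANOVA R²).

The cell summary is the arithmetic mean of the replicates (the point
estimate is the mean of the bootstrap distribution, not the full-data
statistic) with linear-interpolation percentile bounds at the configured
level (default 95%).  `ci_width_decrease` averages the fractional width
change between two depths over matched cells, as a percentage.

**Determinism.**  Every cell derives an independent seed stream from the
master seed and its own factor levels (a CRC of the cell key mixed into a
`SeedSequence`), and each replicate gets a spawned child stream.  Identical
configurations therefore give bit-identical replicate sets and CI records,
independent of cell iteration order — asserted in the tests.

## Neutral drift

A census community of `N` individuals evolves by Wright-Fisher resampling:
one multinomial draw of size `N` per generation with probabilities
proportional to current abundances.  This is the simplest faithful model of
"resampling the community with replacement each generation": population
size is conserved exactly, there is no immigration or speciation (extinct
taxa keep zero rows, richness can only fall), expected relative abundances
are a martingale, and heterozygosity decays by `(1 − 1/N)` per generation in
expectation — all four properties are tested, the latter two against the
closed forms at N = 1000.

Read sampling from the census uses multinomial (with-replacement) draws; at
depths ≤ 2% of a five-million-individual community the difference from a
hypergeometric census subsample is negligible, and with-replacement keeps
the sampler fast and the binomial test targets exact.

The detectability experiment derives two communities by independent drift
streams branching from one seed community, samples both at each
(depth × samples-per-community) cell, and runs the ANOSIM permutation test
(default 1000 permutations) on raw counts — no normalization, no
rarefaction.  The default census is a lognormal stand-in with 954 taxa and
5 × 10⁶ individuals (the taxa count is a free parameter; a real OTU table
can seed the community instead via `Community.from_count_column` or the
CLI's `--seed-table`).  Ordination plots are out of scope; detectability is
quantified by R and p alone.

## Synthetic data generator

The generator emulates the statistical structure of FFE amplicon case
studies, not any particular dataset:

- **Rank abundance**: lognormal taxon weights (default sigma = 2.0, n = 500
  taxa) giving a few dominant taxa and a long rare tail.
- **Within-group variation**: each sample perturbs its group's weights by
  `exp(sample_sigma · z)`, z standard normal (default sample_sigma = 1.0).
  This parameter exists because without within-group compositional noise,
  multinomial counting error alone is negligible at 20,000 reads and *any*
  nonzero group effect saturates ANOSIM at R = 1; realistic effect-size
  regimes (R well below 1 with biologically plausible scatter) require it.
- **Depths**: fixed 20,000 reads/sample by default (matching the deepest
  grid point, and making rarefaction tests exact), with a negative-binomial
  option for heterogeneous depths.
- **Effect modes**: `null` (no signal); `specialist` (a small set of
  abundant taxa enriched `× exp(+s)` in its own group, depleted elsewhere —
  a shallow-detectable signal); `rare_turnover` (disjoint group-specific
  presence/absence sets within the rare tail, defined as taxa below the
  median base abundance — a depth-dependent signal).  `effect_strength = 0`
  reduces both modes to `null` exactly under the same seed, because every
  stochastic stage draws from its own spawned RNG stream.
- **Hierarchy**: random pairwise agglomeration to a target cluster count of
  `round((1−f)·n_taxa)` per level, merging whole previous-level clusters so
  refinement consistency holds by construction; cluster labels are the first
  member's identifier, so an unmerged level is the identity.

**Preset calibration.**  The published regime anchors are bounds, not
generative parameters, so the preset effect strengths were fixed once by a
grid search (over strength, across 20 generator seeds, full-data ANOSIM R
and PERMANOVA R² on CSS-normalized Bray-Curtis) and frozen as constants:
`strong` (specialist, s = 1.0, 24 + 14 samples) lands in the
high-dissimilarity regime (R > 0.70, R² > 0.17) and `weak` (specialist,
s = 0.20, 60 + 60 samples) in the low-dissimilarity regime (R < 0.4,
R² < 0.07) across all seeds examined.  `rare-turnover` assigns half of the
rare tail to group-specific sets (20 + 20 samples).

## The rare-taxon depth contrast

The depth-sweep analysis of rare-turnover data contrasts the fractional
CI-width decrease (depth 100 → 20,000) of Bray-Curtis against binary
Jaccard.  This package's canonical configuration for that contrast uses the
**PERMANOVA R²** statistic, averaged over 10 generator seeds.  The reason
is structural: with a pure presence/absence turnover between two groups,
any turnover large enough to register in Bray-Curtis separates the Jaccard
presence sets almost completely at deep sequencing, so the *rank-based*
ANOSIM statistic on Jaccard saturates at R = 1 with zero CI width — the
saturated metric trivially "wins" any width comparison, which measures
ceiling effects rather than precision.  R² responds to both the signal and
the noise level of the dissimilarities, and in that regime the
abundance-weighted metric's precision gain from depth exceeds the presence
metric's (whose interval keeps responding — and can widen — as the rare
tail comes into view).  Both directions reported by the acceptance checks
(the width contrast and the rise of mean effect size with depth) are
computed, not asserted from expectation.

## Problem sizes

Defaults follow the study conditions (1000 bootstrap replicates, 1000
permutations, five-million-individual census).  The test suite and the
acceptance script scale repetition counts down — 200 bootstrap replicates
per sweep cell, 10–20 seeded repetitions per Monte-Carlo property, 1000
replicate drift runs at N = 1000 — sizes chosen so the full suite completes
in a few minutes while keeping each Monte-Carlo check's standard error well
inside its assertion margin.

## What passing tests do and do not show

The generator reproduces long-tailed rank abundance, within-group
compositional scatter, group effects carried by abundant or rare taxa, and
heterogeneous or fixed depths.  It does not simulate reads (no chimeras,
sequencing error, mistagging, or contamination), spatial structure beyond
exchangeable groups, distance-decay gradients, or taxon-taxon correlations.
Passing tests therefore demonstrate that the *analysis machinery* behaves
correctly and that the documented qualitative trends hold under the stated
generative assumptions — not that any particular real dataset would show
them with the same magnitudes.

## Known limitations

- One-way designs only; multi-factor and nested designs are out of scope.
- CSS uses a fixed quantile; the adaptive-quantile variant is not
  implemented.
- The Jaccard presence threshold is strictly positive with no abundance
  floor.
- Bootstrap-with-replacement inflates ANOSIM R slightly at efforts close to
  or above the group size (duplicate pairs at distance 0 lower within-group
  ranks); this bias is inherent to the resampling design and is visible in
  null-preset sweeps as a small positive mean R at high effort.
- No multiplicity control is applied across sweep cells.
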