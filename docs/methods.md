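# Methods

## Scope and data model

The pipeline takes a fecal 16S amplicon dataset after upstream ASV
calling: a sample×ASV count table, a seven-rank taxonomy
(domain…species, SILVA-style `d__…; p__…` strings accepted), a rooted
phylogeny over the ASVs, per-ASV predicted KO gene-copy numbers, a
pathway→KO catalog, a rank/taxon-name trait database, and sample
metadata. Upstream read processing (denoising, taxonomic classification,
gene-content prediction) is out of scope; those artifacts are input
contracts, validated structurally (`bundle_io.validate_bundle`) but not
recomputed.

All stochastic operations take an explicit seed; there is no global
random state. The orchestrator (`pipeline.run_pipeline`) derives one
independent child seed per stochastic stage from the master seed via
`numpy.random.SeedSequence.spawn`, and the run manifest records the
master seed, parameters, and SHA-256 hashes of every input and output.

## Cohort stage

Exclusions are ordered filters on metadata columns; a sample matched by
an earlier filter is not recounted later, so overlapping criteria are
handled correctly even though the default study shape (220 enrolled,
79 antibiotic users, 22 missing stoma status, 119 analyzed) has disjoint
sets. Exclusion precedes rarefaction; the order is a configuration
choice.

Rarefaction draws an exact without-replacement subsample per sample
(multivariate hypergeometric), at the minimum sample total by default.
Each sample's draw is seeded by the pair (master seed, CRC-32 of the
sample id), so results do not depend on the order samples appear in the
table.

Baseline summaries use Welch's t (numeric), Fisher's exact test
(two-level categorical) or Pearson's chi-squared (multi-level).
Percentages use non-missing denominators, rounded to integers, with
missing counts reported separately — this matters because missingness
differs between groups in real cohorts.

## Trait annotation and category comparison

The database walk tries *species, genus, order, class, phylum* in that
order and adopts the first hit; a database value of `Various` is adopted
as-is, and a feature with no hit at any rank is `Unknown`. The walk
deliberately omits the family rank by default (an `insert_family` flag
adds it after genus); the five-rank order is the annotation convention
this pipeline standardizes on.

Category proportions per sample (4 categories per axis, including
`Various`/`Unknown`, so rows close to 1) are clr-transformed. Zeros are
replaced multiplicatively with δ = 65% of the smallest nonzero proportion
in the matrix (configurable), rows renormalized before logging; the
replacement value is recorded in output metadata. Groups are compared
per category with Mann-Whitney U and Cohen's *d* (stoma minus
non-stoma, (n−1)-weighted pooled SD), BH-corrected within the
four-category family of each axis.

## Diversity

* Observed = count of features with abundance strictly > 0 (this
  definition is reused verbatim at KO and pathway level, where exact
  zeros arise when no carrying feature is present).
* Shannon uses log base 2.
* Faith's PD is the summed branch length of the union of root-to-tip
  paths of observed features, by one post-order pass.
* UniFrac is computed from a tips×branches incidence matrix: per-branch
  descendant proportions per sample in one matrix product, then either
  the shared/union observed-branch-length ratio (unweighted) or
  Σ L·|pA − pB| (weighted, classic non-normalized; a `normalized` flag
  divides by Σ L·(pA + pB)).
* PCoA eigendecomposes the double-centered −d²/2 matrix; axes with
  positive eigenvalues are kept and the summed magnitude of negative
  eigenvalues is reported rather than silently dropped.
* PERMANOVA uses the standard pseudo-F from within/between squared
  distances and p = (#{F_perm ≥ F_obs} + 1)/(n_perm + 1), default 999
  permutations.
* The seven alpha indices (ASV observed/Shannon/PD, KO observed/Shannon,
  pathway observed/Shannon) are compared between groups with
  Mann-Whitney U + Cohen's *d*, BH-corrected jointly across the indices
  passed in — the family is the set of indices compared together.

Mann-Whitney uses exact enumeration when n_a·n_b ≤ 400 and the pooled
data are tie-free, otherwise the normal approximation with tie and
continuity corrections; Fisher's exact p sums hypergeometric
probabilities ≤ the observed table's probability with a 1e-12 relative
tie tolerance.

## Compositional differential abundance

Counts (optionally aggregated to a taxonomic rank by lineage-prefix
summation, with empty-rank features pooled as "unassigned at rank") are
turned into n_mc = 128 Monte-Carlo instances per sample from
Dirichlet(counts + 0.5), each clr-transformed. Per instance, a two-sided
Wilcoxon rank-sum test runs per feature (normal approximation — the clr
values are continuous) and is BH-adjusted across features; eBH is the
per-feature mean over instances. The standardized effect is the median
over instances of Δ/σ with Δ the difference of group medians and σ the
larger within-group median absolute deviation (floored at 1e-8). This is
a simplified, fully-specified effect size rather than the original
tool's sampled between/within quotient; the decision thresholds
(eBH < 0.3, |effect| > 0.17) were calibrated to the original tool and
are kept as defaults with that caveat.

Two numerical properties worth knowing:

* The prior breaks exact scale invariance; doubling all counts moves
  effects by less than Monte-Carlo jitter (asserted in the tests with a
  0.05 + 5 % band).
* Under a label-split null the effect estimate has sampling standard
  deviation ≈ 1.25·√(1/n_a + 1/n_b) (the median's efficiency times the
  two-group variance), i.e. ~0.3–0.4 at this study's group sizes. Null
  effects are therefore *not* concentrated near zero even when no signal
  exists; what is controlled — and what the tests assert — is the rate
  of threshold-crossing *calls*.

KO- and pathway-level differential abundance feed the projected relative
abundances scaled by the rarefaction depth into the same machinery, so
that the Dirichlet uncertainty model sees magnitudes comparable to read
counts.

## Enrichment

KO effect sizes are ranked descending (ties broken lexicographically by
KO id for determinism). The ES is the signed maximum deviation of the
running sum with hit increments |score|¹ (normalized over hits) and miss
decrements 1/(N − N_hits). The null is the ES of random same-size KO
sets (gene-label permutation, default 1000), p is the one-sided tail on
the observed sign with +1 smoothing, NES divides by the mean |null ES|
of that sign, and BH runs across the retained pathways (size filter
3 ≤ |set ∩ list| ≤ N − 1). Weight 1, gene-label permutation and the
smoothing match the common preranked defaults. Note ES is *not*
invariant to adding a constant to all scores at weight 1 (only at
weight 0); the tests assert this deliberately, as it is a common
implementation error.

## Presence attribution

A feature is present when its abundance is > 0 in the (post-rarefaction)
table; fractions pool both groups. Classes: Common iff fraction > 0.99,
Rare iff < 0.01, else Uncommon — boundary values land in Uncommon.
Per-feature 2×2 Fisher tests (present/absent × group) use raw p < 0.05
for the significance callout. The attribution summary reports, per
class: feature count, Fisher-significant count, median
differential-abundance effect, and — for Uncommon — whether the median
effect's sign agrees with the sign of the group difference (stoma minus
non-stoma medians) of the matching diversity index (ASV Shannon for
genera, pathway Shannon for pathways). A zero median or zero diversity
difference is reported as indeterminate rather than forced.

## Synthetic communities

The generator produces the *whole* input bundle so every stage is
testable without external data. Structure:

* **Phylogeny** — four clades joined pairwise at the root: anaerobic
  bacteria (θ·n_taxa tips), other bacteria, aerobic "invaders", and
  archaeal methanogens. Topology is random pair-merging; every branch
  gets an i.i.d. exponential length (scale 0.1) so that losing a tip
  loses measurable phylogenetic diversity.
* **Taxonomy/traits** — one synthetic genus per 1–2 ASVs; ~80 % of
  bacterial genera have a genus-level trait record, ~7 % are annotated
  only at order level, ~6 % are `Various`, ~7 % absent (`Unknown`), and
  a few species-level records override their genus — exercising every
  branch of the annotation walk. The generator also emits the intended
  ground-truth assignment, and a test asserts the annotation operation
  reproduces it exactly.
* **Gene content** — 400 housekeeping KOs carried by every taxon with
  mild copy-number variation (Poisson(1)+1), 10 degradation KOs
  exclusive to invaders, 10 methane KOs exclusive to archaea; the
  catalog holds 5 housekeeping pathways, 3 degradation pathways and one
  methane pathway. The two exclusive blocks are kept the same size and
  comparable abundance on purpose: group-exclusive features swing the
  per-sample clr geometric mean, and unbalanced blocks would shift every
  housekeeping KO's apparent effect.
* **Counts** — per-taxon base abundances are log-normal (σ = 1.2);
  each sample adds i.i.d. per-taxon log-normal biological variability
  (σ = 0.7) and is then drawn Dirichlet-multinomial (precision 200,
  representing residual technical noise) at a depth uniform on
  [42 292, 84 584]. Stoma samples multiply anaerobes by a per-sample
  depletion factor whose log is log(δ)·LogNormal(0, 0.4) — so δ = 1
  (the null) stays exactly 1 — zero a fixed set of r taxa drawn from the
  rare tail of the base-abundance distribution, boost invaders by 1/δ,
  and carry no archaea; non-stoma samples carry no invaders. Per-sample
  effect heterogeneity is essential: with a deterministic group shift,
  within-group variance of aggregated quantities collapses and
  standardized effects diverge, which no real cohort shows. Rare-tail
  (rather than uniform) taxon loss keeps the structural zeros from
  dragging the stoma geometric mean so far that surviving depleted taxa
  appear enriched on the clr scale.
* **Preset** — the defaults are the study-shaped preset: n_taxa = 150,
  θ = 0.6, δ = 0.25, r = 30, 8 invaders, 4 archaea (~1.5 % share),
  21/98 analyzed plus 79 planted antibiotic users and 22 missing-status
  samples (the consort arithmetic is exact by construction). A
  `null_config` preset sets δ = 1 and removes every planted effect; the
  two groups are then exchangeable by construction and the calibration
  tests exploit that.

What the generator does **not** emulate: real phylogenetic signal in
trait distributions beyond clade blocks, covariation between taxa
(interactions), depth-dependent taxon detection bias, chimeras or
contamination, and the long-tailed richness of real gut communities
(thousands of ASVs; here ~160). Passing tests therefore demonstrate that
the machinery recovers planted structure of realistic magnitude at study
sample sizes — not that real data will show effects of these sizes.

## Problem sizes in the test suite

The suite runs the study-shaped preset end to end at its native size
(119 analyzed samples). Replicated checks use reduced problem sizes
chosen for stable Monte-Carlo estimates: null calibration at 15/15
samples × 250–300 replicates (plus 200 replicates each for the
differential-abundance and enrichment nulls), planted-effect recovery at
the study's 21/98 split × 200 replicates and 20/20 × 100 replicates, and
the headline-contrast recovery over 100 preset seeds with 32 Monte-Carlo
instances per differential-abundance call. Calibration assertions bound
empirical rates by nominal + 2 Monte-Carlo standard errors.

## Known limitations

* The differential-abundance effect size is a simplified stand-in for
  the original tool's; the 0.17 threshold inherits that tool's
  calibration and should be revisited if the effect definition changes.
* PERMANOVA assumes exchangeability under the null; with strongly
  unbalanced dispersions it conflates location and dispersion effects.
* The genus–pathway z-scores standardize per pathway across genera (the
  "which genus carries this pathway" reading); per-genus standardization
  across pathways is the other defensible reading and is not provided.
* Percentile boundaries for presence classes are exact inequalities;
  with few samples the Common class can be empty purely through one
  missing observation.
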