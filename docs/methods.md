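# Methods

This note records the models, conventions and numerical choices behind
`coabund`, and what the synthetic validation does and does not demonstrate.

## Quantitation model

Isobaric-label (TMT10) quantitation is relative within one plex. The
package assumes one pooled-reference channel per plex and works throughout
on ratio-to-reference values. `ingest.reference_ratios` divides each
biological channel by the reference and *drops* proteins whose reference
intensity is zero or missing, with a logged count — a ratio cannot be
formed for them, and silent loss is forbidden by contract. Merging takes
the union of proteins across plexes; a protein absent from a plex is
missing (NaN) in that plex's nine biological columns. No imputation is
performed at ingest; each downstream operation declares its own missing
policy (pairwise deletion for the t test, complete-case rows for PCA,
pairwise-complete correlation with a minimum of 3 shared samples for the
network, per-protein mean imputation flagged by count for eigenprotein
SVD only).

Log base 2 is used for the log transform. The t statistic, p-value and
up/down calls are invariant to the base; only the printed `log2fc` column
depends on it. The default missingness threshold is complete-case
(`max_missing_fraction = 0`), configurable.

## Differential abundance

Two-sample two-sided Student t with pooled variance on log2 ratios (Welch
available behind a flag). Fold change is the geometric-mean ratio
`2**(mean_b − mean_a)`. Calls require jointly `FC > fc_up` and
`p < p_cut` (up), or `FC < fc_down` and `p < p_cut` (down); defaults
`fc_up = 1.2`, `fc_down = 1/1.2 ≈ 0.8333`, `p_cut = 0.05`. `fc_down`
is the log-symmetric reciprocal rather than a printed 0.83; the
rounded-threshold variant can be passed explicitly. No multiple-testing
correction is applied to per-timepoint calls by default — the joint gate
is the specificity control, which suits ratio-compressed TMT data;
Benjamini–Hochberg and Holm adjusters are available in `enrich`.

Degenerate cases: a group reduced below 2 observed values is
`untestable`; zero pooled variance with equal means gives `t = 0`
(`p = 1`); zero pooled variance with unequal means is `untestable`
rather than infinitely significant. The per-protein one-way ANOVA follows
the same conventions (groups with < 2 values are excluded per protein; a
protein with < 2 usable groups is untestable with a reason string).

The default contrast is each disease timepoint against the grouped
controls; timepoint-matched controls can be expressed with an explicit
`ComparisonSpec` — both layouts are supported, neither is inferred.

## Network analysis

* **Correlation**: Pearson, pairwise-complete, minimum 3 shared samples;
  pairs below that minimum and zero-variance proteins get missing
  correlations which enter the adjacency as 0 (logged).
* **Adjacency**: signed transform `((1 + r)/2)**beta`. A literal even
  power of the raw correlation would erase the sign and make strong
  anticorrelation look like strong similarity, contradicting the notion of
  a signed network, so the standard signed transform is the default; the
  absolute-value variant `|r|**beta` is available as
  `adjacency_variant="absolute"`. Neither variant is claimed to replicate
  any specific published run bit-for-bit.
* **Soft power**: smallest integer in 1..20 whose binned log–log
  connectivity fit reaches signed `R² ≥ 0.85` (10 equal-width bins,
  frequency regressed on bin-mean connectivity, sign chosen so a
  decreasing distribution is positive). If no power reaches the cut the
  argmax is used and flagged. Fits with fewer than 3 usable bins are
  undefined and flagged.
* **TOM**: standard unsigned formula on the off-diagonal adjacency,
  computed with a matrix product; equality with a triple-loop oracle to
  1e-10 is asserted in the acceptance suite. Distance is `1 − TOM`.
* **Clustering**: UPGMA via `scipy.cluster.hierarchy.linkage` on the
  condensed distance. scipy's nearest-neighbor-chain implementation is
  deterministic for tied distances; dendrograms are therefore reproducible
  byte-for-byte.
* **Dynamic hybrid cut**: branches are grown bottom-up through the merge
  list. At each join a branch qualifies as a module if (i) it has at least
  `min_cluster_size` members, (ii) its core scatter — the mean of its
  lowest `min_cluster_size − 1` internal merge heights — is below
  `ref + 0.82·(cut − ref)`, and (iii) the gap between the join height and
  the core scatter exceeds `0.135·(cut − ref)`, where `ref` is the 5th
  percentile of merge heights and `cut = ref + 0.99·(max − ref)`. The
  0.82/0.135 pair corresponds to the middle split-sensitivity setting of
  the published hybrid procedure; other settings are exposed via
  `deep_split`. When a qualifying branch is finalised, members that
  chained onto it above the core-scatter cap are trimmed back to
  unassigned — without this, diffuse background proteins that attach just
  below the cut height swell every module. A PAM-like second stage then
  assigns each unlabelled protein to its nearest module by average TOM
  distance, provided it falls within that module's assignment radius (the
  maximum average within-module distance of its members). Everything else
  is grey.
* **Labels**: module colour names follow the conventional sequence in
  decreasing size order with ties broken by smallest member index; they
  are presentation only and never join keys.
* **Eigenproteins**: member profiles are standardised (mean 0, sd 1
  across samples) and the first right-singular vector taken; the sign is
  fixed so the mean member correlation is non-negative; explained variance
  is `σ₁²/Σσ²`. kME is the Pearson correlation of every protein (not only
  members) with every eigenprotein; hubs are members ranked by own-module
  kME.
* **Temporal profiles**: per protein, mean log2 ratio per
  (genotype, timepoint) group minus the reference-group mean; per module
  the distribution is summarised by median, quartiles, and whiskers at
  1.5 × IQR clipped to the data range.

## Enrichment

The contingency table is (overlap x, module m, marker K, background N)
with the background always an explicit user-supplied list (e.g. all
module-assigned proteins), never the annotation universe. Marker sets are
intersected with the background first; emptied sets are dropped with a
log entry. Enrichment ratio is observed/expected overlap `x·N/(m·K)` —
recorded as this package's definition since "enrichment ratio" is not
standardised; depletion is representable as ratios below 1. The two-sided
Fisher p uses the probability-mass rule (sum of outcomes no more likely
than observed, with 1e-7 relative slack for float ties), matching
mainstream statistics libraries; ORA uses the upper-tail hypergeometric
`P(X ≥ x)` with BH adjustment across sets. Holm and BH are step-down /
step-up with input order preserved and capping at 1.

Exact tests on discrete 2×2 tables are conservative: under a permutation
null the rejection rate at nominal 0.05 is typically 0.01–0.04 depending
on the margins. The calibration test therefore asserts size control
(rate ≤ nominal + Monte-Carlo slack, and > 0), not equality with 0.05.

## Cross-dataset comparison

Joins are case-insensitive on gene symbol by default (mouse/human
orthographic convention); an explicit two-column mapping table overrides
for non-trivial orthology. One-to-many collisions keep all pairs with a
flag. The association universe is the genes present in both clusterings;
"unassigned" is kept in the tables but excluded from hypothesis testing by
default (a switch includes it). Percent similarity divides the overlap by
the smaller cluster (alternatives `a` and `jaccard` are selectable).
Cluster-pair tests are two-sided Fisher with Holm correction across all
tested pairs and a significance flag at adjusted p < 0.001; degenerate
pairs (a cluster equal to the whole universe or empty) get p = 1 and a
flag rather than an error.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* of a 5-plex longitudinal design:
45 biological samples (5 per group; 4 control and 5 disease timepoints
including recovery), TMT10 channel labels with the pooled reference in
channel 131, randomised sample-to-plex placement (a confounded layout is
also configurable), planted co-abundance modules with archetypal
genotype×time profiles (transient early up; progressive down with partial
recovery; late up persisting; early maintained up; late up with partial
reversal; an age-associated ramp affecting both genotypes), protein-level
plex batch offsets, log-normal measurement noise, and protein-by-plex
missingness (a missing protein drops out of all nine biological channels
of that plex, as unidentified proteins do).

Module structure is a single latent factor per module: member i has log2
signal `b_i + shift(genotype, time) + l_i·σ_m·z_m(s) + π_{i,plex} + ε`,
with loadings `l_i ~ U(0.5, 1)` (a configurable fraction may be negative;
default 0 keeps planted modules coherent under the signed adjacency).
`σ_m` is derived from the configured within-module correlation target
(default 0.7) at the configured noise level; an explicit `module_factor_sd`
override decouples the factor scale from the noise, which is how the
monotone "more noise, less correlation" property is exercised. The
reference channel is the noiseless pooled mean of control-condition
expectations (a noisy-reference flag exists), which makes the zero-noise,
zero-effect configuration produce exactly unit ratios — isolating the
ratio arithmetic from the simulation. Per-plex offsets are drawn per
(protein, plex) and applied to biological channels only: a single global
offset per plex would cancel exactly in the ratio to that plex's own
reference, leaving `plex_effect_sd` inert.

Defaults (2,000 proteins; modules of 150/120/100/80/50/30; noise sd 0.3;
plex effect sd 0.1; no missingness; planted effect 0.585 log2 ≈ 1.5-fold)
are the package's standing validation conditions. With 45 samples the
*mean absolute* pairwise correlation among independent background proteins
is ~0.12 by sampling alone (E|r| ≈ √(2/π(n−1))), so background checks use
the mean *signed* correlation (≈ 0), which is the quantity that actually
distinguishes planted structure from none.

What passing these tests shows: the chain recovers planted block
structure, calibrates its null, and detects full-strength shifts. What it
does not show: robustness to peptide-level artefacts (isotopic impurity,
ratio compression, shared peptides), non-Gaussian noise, correlated
missingness, or modules with non-factor geometry — none of which the
generator models (simulation starts at protein-level channel
intensities).

Two calibration scenarios intentionally simplify further: the
null-calibration and sensitivity datasets switch off the shared module
factor and plex offsets, because they validate the *t statistic* against
its closed-form sampling model (independent observations). With the
module factor left on, whole modules shift coherently between groups and
per-protein sensitivity fluctuates — that regime is covered by the
module-recovery test instead.

## Problem sizes and determinism

Validation runs use 2,000-protein networks (five seeds), a 10,000-protein
null, a 3,000-protein sensitivity panel, enumeration grids up to N = 200,
and 100 permutation draws for cross-clustering — sizes at which every
check completes in seconds while leaving the tested code paths identical
to larger runs. All randomness flows from one seed through named
sub-streams (`numpy.random.SeedSequence.spawn`), so changing one
component's draws does not perturb another's; identical configuration and
seed reproduce every output file byte-for-byte (floats are serialised at
12 significant digits, and the manifest records SHA-256 hashes to make
this checkable).

## Known limitations

* The dynamic hybrid cut follows the published procedure's structure
  (size, core scatter, gap, trim, PAM stage) but is not a line-for-line
  port; on dendrograms with very gradual branch separation its grey set
  may differ from other implementations.
* Pearson correlation only; robust alternatives (biweight midcorrelation)
  are out of scope.
* No module merging by eigenprotein correlation, no preservation
  statistics, no consensus networks.
* The enrichment ratio definition (observed/expected) is an assumption
  where conventions differ.
* GO term databases, redundancy pruning and symbol-aliasing services are
  out of scope: annotation sets enter only as user-supplied GMT files.
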