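# coabund

Analysis of **longitudinal multiplexed (TMT) proteomics**: reference-ratio
quantitation, per-timepoint differential abundance, weighted co-abundance
network analysis, marker-set enrichment, and cross-dataset module
concordance — with a synthetic-data generator that plants known structure so
every stage can be validated end to end.

## Who this is for

Experiments that profile a tissue proteome over disease progression
typically run several TMT10 plexes (one mass-spec run each), dedicate one
channel per plex to a pooled reference sample, and express every protein in
every biological channel as a **ratio to that reference** so plexes become
comparable. Downstream questions are then:

* which proteins change at each timepoint relative to controls
  (differential abundance),
* which proteins move **together** over the time course (co-abundance
  modules), what summarises each module (eigenprotein) and which proteins
  are its hubs (kME),
* whether modules are enriched for marker sets (e.g. cell-type–specific
  proteins), and
* whether alterations and module structure are concordant with independent
  datasets (e.g. another species' post-mortem tissue).

`coabund` implements this whole chain as a typed, tested Python library.

## The statistics at the core

**Quantitation.** For plex $p$ with reference channel $r$:
$\text{ratio}_{i,c} = I_{i,c} / I_{i,r}$ per protein $i$ and channel $c$;
plexes are merged over the union of proteins, filtered by a missingness
threshold, and log2-transformed.

**Differential abundance.** Two-sided two-sample Student $t$ (pooled
variance) on log2 ratios; the overall fold change is the geometric mean
ratio $\mathrm{FC} = 2^{\bar y_B - \bar y_A}$. A protein is called changed
only when it jointly passes $\mathrm{FC} > 1.2$ (or $< 1/1.2$) **and**
$p < 0.05$ — a deliberate alternative to multiple-testing correction under
TMT ratio compression. A per-protein one-way ANOVA across all groups is
also provided.

**Co-abundance network.** Pearson correlation $r_{ij}$ between protein
profiles; signed adjacency $a_{ij} = ((1 + r_{ij})/2)^\beta$ with $\beta$
the smallest power whose connectivity distribution fits scale-free topology
(signed $R^2 \ge 0.85$); topological overlap

$$\mathrm{TOM}_{ij} = \frac{\ell_{ij} + a_{ij}}{\min(k_i, k_j) + 1 - a_{ij}},
\qquad \ell_{ij} = \sum_{u \ne i,j} a_{iu} a_{uj};$$

average-linkage clustering of $1 - \mathrm{TOM}$; **dynamic hybrid tree
cut** (minimum module size 20, core-scatter/gap branch criteria, PAM-like
second stage) into modules with unassigned proteins labelled grey; module
**eigenproteins** as the first right-singular vector of the standardised
member submatrix; **kME** as the correlation of each protein with each
eigenprotein.

**Enrichment.** For background $N$, module $m$, marker set $K$, overlap
$x$: enrichment ratio $xN/(mK)$ with a two-sided Fisher exact test;
generic over-representation uses the upper-tail hypergeometric test with
Benjamini–Hochberg adjustment; Holm correction is available for
family-wise control.

**Cross-dataset comparison.** Case-insensitive gene-symbol joins
(`Stmn2` ↔ `STMN2`), exclusive set intersections, direction-of-change
concordance, and cluster-pair Fisher association with Holm correction
(pairs flagged at adjusted $p < 0.001$).

## Worked example

`examples/03_network_modules.py` simulates the default study-like dataset
(2,000 proteins, six planted modules, 45 samples in 5 plexes) and runs the
full network chain:

```
soft power: 13 (scale-free R^2 target reached)

detected 6 modules (551/2000 proteins assigned, rest grey):
turquoise    157
blue         123
brown        107
yellow        83
green         51
red           30

adjusted Rand index vs planted modules: 0.967 (1.0 = perfect recovery)

top-3 hub proteins per module (by own-module kME):
  turquoise  eigenprotein explains 68% of member variance: P00148 (0.931), ...
```

The six detected modules match the six planted ones (sizes 150/120/100/80/
50/30 plus a little absorbed background); the adjusted Rand index of 0.967
says the partition is nearly identical to the truth, and hub kME values
near 0.95 identify the proteins most representative of each module's
temporal profile. The other scripts in `examples/` walk through
simulation, differential abundance, marker enrichment, cross-dataset
concordance, and the one-command pipeline (`06_full_pipeline.py`), each
printing the numbers it computes and what they mean.

A thin CLI mirrors the library for shell use:

```bash
coabund simulate --out sim --seed 42
coabund prep --design sim/design.tsv --plex plex1 sim/intensities_plex1.tsv ... --out log2.tsv
coabund de --matrix log2.tsv --design sim/design.tsv --timepoint 6wk --out de_6wk.tsv
coabund run --config pipeline.yaml
```

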