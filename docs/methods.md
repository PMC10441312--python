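# Methods

## The analysis model

An optical pooled screen measures, for each single cell, a vector of
morphological features (intensity, texture, granularity, correlation,
radial distribution, shape) across five stain channels, plus the identity
of the CRISPR guide expressed in that cell, decoded from in situ sequencing
of the guide sequence itself. The analysis treats guides as the unit of
replication and genes as the unit of inference:

1. **Aggregation.** Single cells are median-aggregated to one profile per
   (guide, plate). Medians rather than means because single-cell feature
   distributions are heavy-tailed and contaminated by segmentation errors.
2. **Normalization.** Per plate and feature, profiles are centered on the
   median and scaled by 1.4826 × the median absolute deviation of the
   *non-targeting* guides on that plate. The consistency constant makes the
   scale estimate the SD under normality, reconciling "scale by the MAD"
   with "scale to the standard deviation"; normalized non-targeting medians
   are exactly 0 per plate (a tested invariant, tolerance 1e-9). Features
   whose non-targeting MAD is zero on a plate carry no usable contrast
   there and are set missing.
3. **Feature selection** (on normalized guide-plate profiles, per screen):
   drop features missing on any plate (they cannot be median-aggregated
   comparably), drop near-constant features (most frequent value > 99% of
   rows — a scale-free rule that survives MAD normalization; threshold
   configurable), then greedily remove redundancy until no retained pair
   has |Pearson r| > 0.9. In each offending pair the feature with the
   larger mean |r| against everything else is dropped; ties break on the
   feature name, so the result is deterministic.
4. **Guide and gene profiles.** Plate rows are median-aggregated per guide,
   guide rows per gene; non-targeting guides collapse to one pseudo-gene
   row that is excluded from gene-level inference.

## Hit calling against an empirical null

Per gene and retained feature, the gene's guide-level values (typically 4)
are compared with the non-targeting guide values (60 at desk scale) by a
two-sided Mann–Whitney U-test, normal approximation with tie and
continuity corrections. Exact enumeration (used as the test oracle)
shows the approximation tracks the exact p within a factor of ~6 and
|Δp| ≤ 0.05 over the relevant sample sizes; at n=4 vs m=60 the smallest
achievable p is ≈ 9.2e-4, so the α = 0.001 per-feature threshold is
reachable only on complete separation of the two samples — the test is
deliberately strict, and **no multiple-testing correction is applied at
the feature level**. Error control happens at the gene level instead:

- profile score `S_g` = number of features with p < 0.001 (strict);
- morphological signal score `M_g` = Σ −log10 p over those features
  (base 10 by convention; every internal comparison is base-consistent, so
  rankings and counts do not depend on the choice);
- the hit threshold T is the empirical 95th percentile (linear
  interpolation between order statistics) of `S_g` among **zero-TPM
  genes** — genes unexpressed in the screened line, whose knockouts are
  phenotypic nulls; a gene is a hit iff `S_g > T` (strictly), so ~5% of
  zero-TPM genes exceed T by construction. Because profile scores are
  small integers, ties at the threshold order statistic push the realized
  exceedance somewhat below 5% — this granularity is inherent to the
  construction, not an implementation artifact.

Compartment hits repeat the construction on the feature subset attributed
to one stain channel: texture, intensity, correlation, radial distribution
and granularity features of that channel. Correlation features count
toward both of their channels; AreaShape features belong to no compartment.
The zero-TPM threshold is recomputed per compartment, so a gene can be a
hit in one or more compartments without being a whole-cell hit.

## Similarity and enrichment

Hit-gene profiles are reduced by PCA to the smallest component count
explaining ≥ 70% of variance (centering only — inputs are already
MAD-scaled; component signs fixed by making each component's
largest-|loading| entry positive). Pairwise Pearson correlations of the
reduced profiles feed: complex recall (complexes with ≥ 2/3 of members
among hits and ≥ 2 present; within-complex vs all-hit-pair correlation
distributions, compared by a rank-based separation statistic), link-score
summaries over 8 equal-width correlation bins, Ward/Euclidean hierarchical
clustering of the correlation-matrix *rows* (the clustermap-on-correlations
convention), cross-screen order transfer into diagonally merged matrices
(lower triangle screen A, upper screen B), and cosine-metric UMAP
(n_neighbors 15, min_dist 0.1, fixed seed).

The preranked enrichment statistic is the weighted Kolmogorov–Smirnov
running sum (hit increments ∝ |ranking value|, miss decrements uniform; ES
is the signed maximum deviation), with a gene-label permutation null
(default 2000 permutations), two-sided p on |ES|, normalization by the
mean same-sign permutation |ES|, and BH across sets. It is implemented
directly so the pipeline is self-contained; its normalization is the
standard formulation, not a re-derivation of any external tool's
internals. Single-feature screens build per-feature "Top 20+" lists (all
genes with p ≤ the 20th-smallest p, ties included), assess term enrichment
with one-sided Fisher exact tests, BH across terms per feature, and an
additional Bonferroni correction across features for term-family screens.
Essentiality splits use a gene-effect threshold of −0.5, with the boundary
value classed essential.

## Barcode library design

Guides are barcoded by their first 12 bases (the sequenced cycles), so the
design constraints live on 12-base prefixes: pairwise distinctness
(complete deconvolution), pairwise Levenshtein distance ≥ 2 (any single
read error is then detectable: a 1-error read maps uniquely back or is
flagged ambiguous, never silently misassigned — verified by exhaustive
single-substitution enumeration), and per-position base balance for
reliable optical base calling. Selection is greedy — genes in seeded random
order, candidates ranked by composition-balance improvement among those
compatible with the already-selected set — which is deterministic given the
seed and auditable; genes with too few compatible candidates are reported,
never silently dropped. Balance is a soft objective (tie-breaker), not a
hard constraint. `N` in reads mismatches every base. Read assignment
accepts the unique nearest prefix within distance 1 by default.

## The synthetic generator

`generate_screen` emulates the statistical structure the analysis assumes:
a pooled library (~4 guides/gene plus a non-targeting pool, 10% of the
library at full scale, 60 guides at desk scale), plates with additive
per-plate feature offsets (SD = 0.3 × cell noise SD, exercising per-plate
normalization), features laid out on the category × channel grid, and
per-cell Gaussian noise (Student-t, df 5, via a config switch for
robustness checks). Perturbation signal has two parts:

- **gene effects**: sparse mean-shift vectors (default 30 features,
  80% drawn from one designated channel, magnitude `effect_size` = 2
  cell-SD units), present only in effect genes (default 80% of expressed
  genes); complex members share a template vector up to a positive scale,
  so their profiles correlate;
- **a cutting signature**: one fixed sparse shift (10% of features,
  0.5 cell-SD) applied to *every targeting guide*, scaled by a per-guide
  efficiency ~ Uniform(0.5, 1), and absent from non-targeting guides. This
  models the generic cellular response to Cas9 cutting: any targeting
  knockout, including one of an unexpressed gene, differs systematically
  from non-targeting controls. It is the reason the empirical hit
  threshold must come from zero-TPM knockouts rather than from
  non-targeting guides — without it, true-null genes would have profile
  scores of almost exactly zero (the 4-vs-60 rank test at α = 0.001
  rejects a true null with probability ~3e-6) and the percentile
  construction would degenerate. The magnitude was set by a separation
  calculation (normalized shift ≈ 2.2 × efficiency against guide-level
  noise ≈ 0.71) so zero-TPM profile scores spread over roughly 0–15,
  giving the 95th percentile meaningful resolution.

Zero-TPM genes (default 50% of genes) have zero gene-effect vectors and
TPM 0; essentiality scores are drawn independently of effect status, so
hit rates should not differ between essential and non-essential genes.
`generate_annotations` derives complex-membership, pairwise link-score
(same-complex pairs higher in expectation), TPM and gene-effect tables.

**What passing tests do not show about real data:** the generator's noise
is independent across features and cells, effects are pure mean shifts,
and guide efficiency is the only guide-level heterogeneity. Real screens
have correlated features, cell-cycle and density covariates, off-target
guides, barcode-calling errors and uneven cell counts; results here
validate the *machinery* (normalization algebra, threshold construction,
rank statistics, audits), not biological effect sizes.

## Problem sizes and numerical choices

The default desk-scale configuration — 200 genes × 4 guides + 60
non-targeting guides, 2 plates, 30 cells/guide/plate (51,600 cells), 300
features — was chosen so a full simulate-through-enrichment run takes
seconds and the entire test suite about a minute on one CPU; the test
fixtures scale genes, cells and features down further but never the
non-targeting pool (the rank test's p-value floor depends on it; below
~60 controls α = 0.001 is unreachable). Medians of even-length samples are
the mean of the two central order statistics. Degenerate cases are
contracts, not accidents: fully tied rank tests return p = 1, constant
control features become missing and fall to the feature-selection
missingness rule, zero-norm profiles are flagged and ranked last in
similarity queries, fewer than 20 zero-TPM genes triggers an instability
warning, and an empty zero-TPM set is an error.

Known limitations: no spherization/whitening, no well-position or
cell-count covariate correction, no ontology DAG handling (term sets are
flat), and the preranked permutation null permutes gene labels (set
membership), not phenotypes.
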