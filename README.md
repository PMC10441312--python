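# morphoscreen

Downstream analysis for **optical pooled CRISPR screens** read out by Cell
Painting-style morphological profiling. In these screens, every cell carries
one guide RNA whose expressed sequence doubles as an optical barcode decoded
by cyclic in situ sequencing, and hundreds to thousands of per-cell
morphological features are measured across five stain channels (DNA, ER,
mitochondria, actin, WGA/Golgi-membrane). `morphoscreen` takes the
single-cell feature table with guide assignments and carries it through to
gene-level biology:

- **profiling** — median aggregation of cells to (guide, plate) profiles,
  per-plate robust normalization against non-targeting controls
  (`x' = (x − median_NT) / (1.4826 · MAD_NT)`), feature selection
  (missingness, near-constant, greedy `|r| > 0.9` redundancy filters), and
  median aggregation to guide- and gene-level profiles;
- **hit calling** — per gene and feature, a two-sided Mann–Whitney U-test of
  the gene's guide profiles against non-targeting guides; the *profile
  score* `S_g = #{f : p_{g,f} < 0.001}` and the *morphological signal
  score* `M_g = Σ_{p<0.001} −log10 p`; hit thresholds set at the 95th
  percentile of profile scores among **zero-TPM genes** (unexpressed genes
  whose knockouts form an empirical null), giving a 5% empirical FDR, for
  the whole-cell profile and per stain-channel compartment;
- **similarity** — PCA to ≥ 70% explained variance, pairwise Pearson
  correlation of hit-gene profiles, protein-complex recall (2/3-coverage
  rule), link-score summaries over 8 correlation bins, Ward/Euclidean
  clustering with cross-screen leaf-order transfer and diagonally merged
  heatmap matrices, cosine-metric UMAP embedding;
- **enrichment** — gene rankings by signal score or by cosine similarity to
  a query gene, a preranked weighted running-sum enrichment statistic with
  a permutation null, per-feature "Top 20+" single-feature screens with
  one-sided Fisher exact tests, Benjamini–Hochberg and Bonferroni
  corrections, and granularity-spectrum traces;
- **library design** — barcode (guide-prefix) selection with complete
  12-base deconvolution, pairwise Levenshtein distance ≥ 2 for error
  detection, balanced per-position base composition, and error-correcting
  read assignment;
- **synthetic data** — a generator producing ground-truth-labelled screens
  (guide libraries, plates, channel-structured features, zero-TPM nulls,
  compartment-biased effect genes, effect-sharing complexes, annotation
  tables) so every stage is testable without downloading anything.

The normalizer, feature selector, PCA reducer and hit caller are
scikit-learn-style estimators (`fit`/`transform`, fitted attributes with
trailing underscores) and compose with sklearn pipelines; module-level
functions wrap them for script use, and a `morphoscreen` CLI orchestrates
end-to-end runs.

## Worked example

```python
import morphoscreen as ms
from morphoscreen.synthetic import ScreenConfig, generate_screen

# 200 genes (100 zero-TPM), 4 guides/gene, 60 non-targeting guides,
# 2 plates, 30 cells/guide/plate, 300 features
cells, feature_meta, library, truth = generate_screen(ScreenConfig(seed=1))

profiles = ms.profile_pipeline(cells)          # cells -> guide/gene profiles
caller = ms.EmpiricalFDRHitCaller().fit(
    profiles["guide_screen"], feature_meta, truth.zero_tpm_genes
)
ht = caller.hit_table_
print("whole-cell threshold:", caller.threshold_)
print("whole-cell hits:", int(ht["whole_cell_hit"].sum()))
print("zero-TPM genes called (%):",
      100 * ht.loc[truth.zero_tpm_genes, "whole_cell_hit"].mean())
print("effect-gene recall:",
      ht.loc[truth.effect_genes, "whole_cell_hit"].mean())
```

prints

```
whole-cell threshold: 7.0
whole-cell hits: 87
zero-TPM genes called (%): 4.0
effect-gene recall: 1.0
```

The threshold 7.0 is the 95th percentile of the profile scores of the 100
zero-TPM null genes; 4 of them exceed it (≈ 5% by construction, below it
here because tied integer scores at the threshold are not counted), and all
80 true effect genes are recovered. From there:

```python
gene = profiles["gene"].set_index("gene")
hits = ht.index[ht["whole_cell_hit"]]
reduced = ms.reduce_pca(gene.loc[hits, profiles["features"]])   # >= 70% var
corr = ms.pairwise_correlation(reduced)
order, linkage = ms.cluster_order(corr)                         # Ward/Euclidean
ranked = ms.rank_by_signal(ht)                                  # for enrichment
```

The same chain runs from a shell:

```bash
morphoscreen run-all --seed 1 --out run1
```

## Layout

| module | contents |
| --- | --- |
| `morphoscreen.synthetic` | `ScreenConfig`, `generate_screen`, `generate_annotations`, `GroundTruth` |
| `morphoscreen.library` | `levenshtein`, `select_barcodes`, `min_deconvolution_prefix`, `match_read`, `base_composition` |
| `morphoscreen.profiling` | aggregations, `RobustMADNormalizer`, `CorrelationFeatureSelector`, `profile_pipeline` |
| `morphoscreen.hits` | `pvalue_matrix`, scores, `call_hits`, `EmpiricalFDRHitCaller`, compartment analyses |
| `morphoscreen.similarity` | `VarianceTargetPCA`, correlations, complex recall, binning, clustering, UMAP |
| `morphoscreen.enrichment` | rankings, preranked enrichment, Top 20+, Fisher screens, granularity, essentiality |
| `morphoscreen.pipeline` / `cli` | config-driven orchestration, manifests, `morphoscreen` command |

See `docs/methods.md` for the statistical model, parameter defaults, and
what the synthetic generator does and does not emulate.
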