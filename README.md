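# plaqomics

Multi-omic integration pipeline for PBMC mRNA, PBMC miRNA and plasma
cytokine/chemokine data from a four-group cohort design
(`CTRL`, `AS`, `HIV`, `HIV_AS`). It implements, as tested reusable code:

- **omics_io** — TSV/GMT readers and writers, the low-count filters
  (exclude features with < N reads in *every* sample), median-of-ratios
  size factors with a `log2(count/sf + 1)` variance-stabilizing transform,
  and geometric-mean collapse of cytokine technical duplicates.
- **diffexpr** — per-feature negative-binomial Wald tests (log link,
  size-factor offsets, method-of-moments dispersions shrunk toward a mean
  trend) with Benjamini–Hochberg correction and threshold filtering.
- **sptf** — single-subject transcription-factor activity scores: PCA of
  each TF's target-gene submatrix, score `sqrt(sum_{i=2..m} s_i^2 v_i)`
  (PC1 excluded; `m` = PC at 50% cumulative variance), per-gene percent
  weights `sqrt(sum_{i=2..m} w_i^2 v_i)/(1 - v_1)`, and Pearson
  correlation of scores with plasma analytes.
- **mirna_integration** — miRNA-target prediction aggregation (≥ 2 of 5
  algorithms), expression anticorrelation filtering (r ≤ −0.5, p < 0.05),
  diagonal-shrinkage LDA ranking of discriminant target genes (top-27
  default), Spearman miRNA–cytokine correlations with significance stars,
  and fold-change quadrant bookkeeping.
- **celltype_atlas** — blood-cell-type miRNA summaries: per-miRNA
  equal-width discretization into `ceil(cbrt(max n))` levels and
  lower-median aggregation per cell type.
- **multiomic_network** — sparse-PLS association scores between omic
  blocks with seeded permutation p-values, per-group network assembly,
  Louvain communities, and differential eigenvector centrality between
  groups.
- **synthetic_cohort** — a seeded generator of NB count matrices,
  duplicate-well cytokine panels, TF gene sets and prediction tables with
  planted DE features, a TF-activity/cytokine axis, miRNA→target
  repression and a group-specific network hub, plus a ground-truth record
  — every downstream stage is testable offline.

## CLI

```sh
plaqomics simulate --seed 7 --out cohort/
plaqomics preprocess --mrna cohort/mrna_counts.tsv --mirna cohort/mirna_counts.tsv \
    --cytokines cohort/cytokines.tsv --groups cohort/sample_groups.tsv --out prep/
plaqomics de --matrix prep/mirna_filtered.tsv --groups cohort/sample_groups.tsv \
    --contrast HIV_AS:HIV --out de.tsv
plaqomics sptf --expr prep/mrna_vst.tsv --groups cohort/sample_groups.tsv \
    --gene-sets cohort/tf_targets.gmt --cytokines cohort/cytokines.tsv --out sptf/
plaqomics mirna-integrate --predictions cohort/mir_predictions.tsv \
    --mirna prep/mirna_vst.tsv --mrna prep/mrna_vst.tsv \
    --groups cohort/sample_groups.tsv --k 27 --out integration/
plaqomics atlas --counts compendium.tsv --labels cell_types.tsv --out atlas.tsv
plaqomics network --mrna prep/mrna_vst.tsv --mirna prep/mirna_vst.tsv \
    --cytokines cohort/cytokines.tsv --groups cohort/sample_groups.tsv \
    --seed 7 --out network/
```

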