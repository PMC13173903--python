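# scstates

Shared cell-state discovery across multi-sample single-nucleus RNA-seq
cohorts, with clinical validation — and a synthetic-data generator that
plants ground truth for every stage so the whole pipeline is testable
offline.

## What it does

Given per-sample cell×gene UMI count matrices from a mixed human/mouse
(xenograft) experiment, the pipeline:

1. **species_qc** — assigns nuclei to species by 10th-percentile UMI
   thresholds, derives read/UMI gates from KDE local minima, applies the
   strict <5% mitochondrial filter, and removes doublets by a dual-method
   consensus rule capped at the expected multiplet count.
2. **preprocess** — variance-stabilises counts as NB Pearson residuals with
   four per-cell covariates regressed out, assigns G1 vs S/G2M phase by
   control-bin scoring, selects PCA dimensionality by a <0.1-percentage-point
   variance-drop elbow, and builds a shared-nearest-neighbour graph.
3. **within_sample_clustering** — clusters each (sample, phase) stratum by
   modularity optimisation, choosing the resolution from a fixed grid that
   minimises a medoid-based Davies–Bouldin index subject to a 3–8 cluster
   band.
4. **meta_clustering** — merges initial clusters across samples via Spearman
   similarity of mean profiles over shared HVGs (variable in ≥3 samples),
   cut by average-linkage hierarchical clustering at similarity 0.75.
5. **marker_aggregation** — one-vs-rest Wilcoxon DE per sample, Fisher's
   combined probability across samples, per-MC BH-FDR, and the marker rule
   (FDR < 0.01, log2FC > log2(1.25) in ≥2 samples, HSP/MT-/RPL excluded);
   top-100 lists per meta cluster.
6. **signatures_enrichment** — overlap coefficient, hypergeometric pathway
   enrichment, a rank-KS per-cell gene-set scorer with state assignment,
   pseudo-bulk signature recipes (mean, negated scaled sum, anchored PC1),
   and the cosine co-expression score.
7. **regulon_specificity** — AUCell-style recovery-curve activity scoring
   and meta-cluster-specific TF calling.
8. **cohort_validation** — median-split prognosis groups, Cox
   proportional-hazards association censored at 10 years, one-sided Wilcoxon
   response tests per arm, and the sample-size-weighted sum-of-z combination.
9. **variant_cna_filters** — the four variant-retention clauses and
   per-sample SD standardisation of copy-number log2 ratios (|z| > 3 calls).

The `synthetic` module generates every input with known truth: barnyard
mixtures with doublets, multi-sample cohorts with planted states, batch
shifts, cell-cycle programmes and QC artefacts, and bulk clinical cohorts
with planted response/survival effects.

## CLI

```bash
scstates run --out runs/demo --seed 0          # simulate + full pipeline
scstates run --config my.yaml --out runs/x     # YAML-configured run
scstates simulate --out sim/ --seed 0          # write MTX triplets + truth
scstates qc sim/sample1 --out qc.tsv           # species + QC on one triplet
scstates filter-variants variants.tsv --out kept.tsv
scstates call-cna segments.tsv --out cna.tsv
scstates validate cohort.tsv sigs.gmt --out assoc.tsv
```

`scstates run` writes per-stage TSVs (QC report, initial clusters,
meta-cluster assignment + Newick dendrogram, marker tables, per-cell
signature scores, cross-phase overlap matrix) and a `manifest.json`; a rerun
with the same parameters reuses the simulation checkpoint.

## Library use

```python
from scstates import PipelineConfig, run_cohort_pipeline
from scstates.synthetic import build_gene_universe, default_states, generate_cohort

universe = build_gene_universe(seed=0)
states = default_states(universe, n_states=4, log2_effect=2.0, seed=0)
adatas, truth = generate_cohort(5, states, cells_per_sample=2000, seed=0)
result = run_cohort_pipeline(adatas, PipelineConfig(seed=0), truth)
result.assignments["G1"].as_frame()    # initial cluster -> meta cluster
result.top_markers["G1"]               # top-100 markers per meta cluster
```
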