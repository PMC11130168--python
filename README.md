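# rsstyper

Discovery and classification of **rectal cancer-specific transcriptional
subtypes (RSS)** from multi-batch gene-expression cohorts.

Generic colorectal subtyping schemes (CMS, CRIS) were trained mostly on colon
tumours, and rectal resections are often profiled *after* neoadjuvant
chemoradiotherapy, which shifts tumours toward a stromal/mesenchymal
expression state. `rsstyper` implements the workflow for deriving subtypes
from treatment-naive rectal samples and deploying them across heterogeneous
cohorts:

1. **Preprocessing** — merge log2 expression studies on their shared genes,
   detect duplicated samples (file checksum or expression correlation r ≥
   0.999), quantile-normalise, and apply a per-gene location–scale batch
   correction.
2. **Subtype discovery** — Monti consensus clustering: repeated 80%
   subsampling, average-linkage clustering of the 1 − Spearman sample
   distance, and co-clustering tallies per candidate k. The cluster count is
   chosen from the relative increase of the area under the consensus CDF,

   Δ(k) = [A(k) − A(k−1)] / A(k−1),

   taking the largest k whose gain is substantial and followed by a collapse
   (the "deltaK" elbow). Silhouette widths and PCA coordinates are emitted as
   diagnostics.
3. **Gene modules** — genes differential between any subtype pair (pooled
   BH-FDR < 0.05) feed a weighted co-expression network: unsigned power
   adjacency a_ij = |ρ_ij|^β (Spearman, β = 6), optional restriction to
   high-connectivity hub genes, topological-overlap dissimilarity

   TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(K_i, K_j) + 1 − a_ij),

   and modules from cutting the gene dendrogram over a sweep of cluster
   counts, with hypergeometric gene-set enrichment pruning and a minimum
   module size of 5.
4. **Classification** — each sample is reduced to per-module **median**
   scores (robust to partial gene coverage) and a gradient-boosted multiclass
   model (XGBoost, depth 3, 200 rounds) is trained with stratified 5-fold
   cross-validation, then applied to new cohorts.
5. **Survival & treatment shift** — Kaplan–Meier curves, the k-group log-rank
   test, TNM stage imputation (missing stage → stage 3 when N > 0 and M = 0),
   and pre/post-treatment subtype transition tables.

A first-class synthetic-cohort generator (`rsstyper.synthetic_cohort`)
produces expression matrices with block-correlated gene modules, planted
subtypes, batch effects, subtype-dependent survival, and matched
pre/post-treatment pairs, so the whole pipeline is testable without any
external data.

## Worked example

```python
from rsstyper.pipeline import RunConfig, run_discovery

manifest = run_discovery(RunConfig(seed=1, out_dir="run"))
print(manifest["metrics"])
```

```
{'k_selected': 3, 'n_modules': 12,
 'min_fold_accuracy': 0.9166666666666666,
 'mean_fold_accuracy': 0.9722222222222221}
```

This simulates the default cohort (180 samples × 2000 genes, 12 planted gene
modules, 3 subtypes at a 1.0 log2 module shift, 4 batches), preprocesses it,
and runs discovery end to end. The deltaK table written to `run/delta_k.csv`
shows why three clusters are selected — the relative area gain collapses
after k = 3:

```
 k  area  delta
 2 0.450  0.450
 3 0.670  0.490
 4 0.679  0.013
 5 0.688  0.013
```

All 12 planted modules are recovered (`run/modules.tsv`), and the five
cross-validation folds of the module-median classifier score 97.2%, 97.2%,
91.7%, 100%, 100% accuracy (`run/cv_metrics.csv`), i.e. above 90% in every
fold, with one-vs-rest AUCs ≥ 0.99.

The same pipeline is scriptable from the shell:

```bash
rsstyper simulate --seed 1 --out data/
rsstyper run-all --seed 1 --out run/
rsstyper classify --model run/model.json --expression cohort.tsv \
                  --annotation cohort_clinical.csv --out predictions/
```

`classify` writes per-sample subtype probabilities and, when the annotation
carries follow-up columns (`time_months`, `event`), Kaplan–Meier tables and a
log-rank report stratified by predicted subtype; matched pre/post pairs
(`pair_id`, `treatment`) additionally produce a subtype-shift table.

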