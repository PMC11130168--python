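# Methods

This note documents the models and procedures implemented in `rsstyper`, the
reasoning behind the tunable parameters, and what the synthetic cohorts do
and do not emulate.

## Synthetic cohort model

Expression of gene *g* in sample *s* is simulated on the log2 scale as

```
x_gs = mu_g + a_{g,b(s)} + c_{g,b(s)} * ( w f_{m(g),s} + delta_{m(g),t(s)} + e_gs )
```

| term | meaning | default |
|---|---|---|
| `mu_g` | baseline gene mean, N(7, 1.5²) log2 units | — |
| `f_{m,s}` | latent module factor, N(0,1) per (module, sample) | 12 modules, 20–120 genes |
| `w` | factor loading (see calibration below) | from `within_module_cor_target = 0.25` |
| `delta_{m,t}` | subtype shift of module *m* in subtype *t*, log2 units | one-hot, 1.0 per module |
| `a_{g,b}` | additive batch offset, N(0, `batch_shift_sd`²) | sd 0.5, 4 batches |
| `c_{g,b}` | multiplicative batch scaling, exp N(0, `batch_scale_sd`²) | sd 0.1 |
| `e_gs` | measurement noise, N(0, `noise_sd`²) | sd 0.5 |

Background genes (those outside the planted modules) carry no factor and no
subtype shift. Subtype and batch labels are balanced and shuffled. Survival
is exponential with per-subtype hazards (default 0.02, 0.05, 0.03 events per
month — the stromal-like subtype 1 has the worst prognosis) under uniform
censoring on (0, 120] months; clinical TNM fields are generated with some
overall stages masked so the stage-imputation rule is exercised.

**Loading calibration.** `within_module_cor_target` is the *baseline*
within-module correlation — the correlation two module genes would show in
the absence of subtype effects. Since noise and batch offsets are independent
between genes,

```
w² = rho/(1−rho) · (noise_sd² + v_batch),   v_batch = (1 − 1/B) · batch_shift_sd²
```

The loading is deliberately independent of the planted subtype effects:
module identity (co-regulation strength) stays fixed while the subtype
contrast is dialled, which keeps module-recovery experiments well posed at
any effect size. Planted shifts add shared variance, so the *pooled*
within-module correlation exceeds the baseline; `expected_within_correlation`
returns the model-implied value (≈ 0.46 Pearson at the defaults) and the test
suite checks measurements against it. The default baseline of 0.25 is typical
of the mean pairwise correlation inside co-expression modules in microarray
cohorts and leaves the 1.0 log2 subtype contrast, rather than factor noise,
as the dominant between-sample signal — the regime in which a module-median
classifier is the right tool.

**Gene architecture vs. sample streams.** The gene→module placement and the
baseline means are drawn from an *architecture* RNG stream keyed by the seed
alone, while factors, noise, batches and survival come from per-cohort
streams. Cohorts and treatment pairs generated at the same seed therefore
describe the same "genes", so a classifier trained on one cohort can
meaningfully score the other; different seeds give fully independent worlds.

**Treatment pairs.** Post-treatment samples equal their pre-treatment mates
plus `shift_effect` (default 1.5 log2 units) on every stromal-module gene
plus fresh measurement noise — an additive stromal activation, consistent
with the fibroblast-expression increase that accompanies the post-therapy
mesenchymal shift. Stromal modules default to those whose planted shift
belongs to the stromal-like subtype.

**What the generator does not emulate:** probe-level effects and
platform-specific probe→gene maps, RNA-seq counts (negative binomial,
library size), heavy-tailed or skewed intensity distributions, correlated
module factors (pathway cross-talk), informative censoring, and confounding
between batch and subtype (batches are balanced by construction). Passing
tests therefore demonstrate the pipeline's correctness and its behaviour
under a Gaussian latent-factor model, not performance on real arrays.

## Preprocessing

- **Duplicate detection**: md5 checksums group byte-identical raw files;
  correlation mode (for matrices without raw files) groups samples with
  pairwise Pearson r ≥ 0.999 by transitive closure and keeps the
  lexicographically smallest identifier.
- **Quantile normalisation** maps every column onto the mean vector of order
  statistics (ties receive the mean of the tied reference values). It stands
  in for full RMA: inputs are assumed already probe-summarised and log2.
- **Batch correction** is a per-gene location–scale adjustment: each batch is
  centred and rescaled to the gene's pooled mean and standard deviation
  (ComBat without empirical-Bayes shrinkage). It is deterministic, exactly
  preserves pooled gene means, and removes the additive/multiplicative batch
  structure the generator produces; it does not borrow strength across genes,
  so very small batches (< 3 samples) are rejected rather than corrected.

## Consensus clustering and deltaK

Sample distance is 1 − Spearman correlation over genes (consistent with the
Spearman-based network stage). For each candidate k, 100 resamples draw 80%
of samples without replacement; each resample is clustered with
average-linkage agglomeration and co-clustering is tallied over the pairs
drawn together. A(k) is the area under the empirical CDF of the
upper-triangle consensus values (trapezoid over sorted values), and
Δ(2) = A(2), Δ(k) = (A(k) − A(k−1))/A(k−1).

**Elbow rule.** The original deltaK selection is visual. It is operationalised
here as: consider every k whose Δ(k) is at least 0.1 absolutely *and* at
least 15% of the largest Δ at k ≥ 3, and whose successor drops below half of
Δ(k); select the largest such k, falling back to argmax Δ when no drop
exists. The relative floor matters because splitting a true cluster still
inflates the consensus CDF area somewhat: after a strong k* the curve shows a
medium Δ(k*+1) whose absolute size scales with the overall signal, so a fixed
threshold alone cannot separate the last informative k from the first
redundant one across effect sizes. The rule recovers planted k ∈ {2, 3, 4}
on simulated cohorts at effect ≥ 1.5.

**Final labels** come from hierarchical clustering of 1 − consensus using
Ward linkage. Average linkage on a fuzzy consensus matrix chains: a single
atypical sample forms its own cluster at the cut and one real group absorbs
the rest. Ward's variance criterion produces balanced groups and recovers the
planted partition exactly (ARI = 1.0) at effect ≥ 1.5.

**Null behaviour caveat.** Consensus clustering is known to report apparent
structure on structureless data: resamples share most samples, so the same
chance splits recur and consensus values polarise, producing sizeable Δ even
for pure noise. The `low_confidence` flag (max Δ(k ≥ 3) < 0.1) therefore
fires only for genuinely near-uniform consensus matrices; a confident-looking
deltaK curve on real data is *not* by itself evidence of subtypes, and the
silhouette/PCA diagnostics should be consulted alongside it.

## Gene-module discovery

- **Subtype-gene filter.** Per gene, a one-way ANOVA (equivalently the
  squared pooled two-sided t) for every pair of subtype labels; a gene is
  kept when significant in *any* pair. BH adjustment runs pooled across all
  pairwise tests by default: adjusting each pair separately and taking the
  union lets the false-discovery rate of the union grow toward three times
  the nominal level under the global null (measured ≈ 0.17 at α = 0.05),
  whereas the pooled adjustment keeps it at ≈ 0.05. Per-pair adjustment
  remains available (`adjust="per_pair"`).
- **Network.** Spearman similarity between genes → unsigned power adjacency
  |ρ|^β. β defaults to the conventional 6; passing `beta=None` picks the
  smallest power in 1..10 whose connectivity distribution fits a scale-free
  law (R² ≥ 0.8, negative slope). Connectivity is the mean adjacency to all
  other genes, so it lies in [0, 1] regardless of network size.
- **Group centring.** When subtype labels are supplied, each gene is centred
  on its group means before correlating. Genes selected *for* between-group
  differences otherwise correlate merely for sharing a group contrast, which
  merges distinct same-subtype modules as the effect grows; centring bases
  module membership on co-regulation proper and makes recovery independent of
  effect size. The pipeline uses it; plain pooled correlation remains the
  default for unlabelled use.
- **Hub restriction.** `restrict_by_connectivity` keeps genes strictly above
  the median connectivity (or an explicit cutoff). On a large, noisy gene set
  this focuses the network on hub genes; on a desk-scale simulated cohort the
  FDR-selected set is already signal-pure and connectivity scales with module
  size, so a median cut removes whole small modules. The pipeline therefore
  leaves restriction off by default and exposes it as configuration.
- **TOM.** Topological-overlap dissimilarity uses unnormalised adjacency row
  sums K_i; entries lie in [0, 1] and the denominator is provably positive
  for adjacency in [0, 1].
- **Tree cut.** An average-linkage dendrogram on the TOM dissimilarity is cut
  at every k in [5, 101] (bounded by the gene count). Because cuts of a
  single dendrogram are *nested*, any co-membership summary over the sweep
  collapses to a single cut: pair co-membership frequency is a monotone
  function of merge height, so thresholding it at a fraction q reproduces the
  cut at the q-quantile k of the sweep. The sweep is therefore resolved by
  keeping the partition with the highest mean silhouette width on the TOM
  dissimilarity (`method="best_k"`); the stability-graph construction is kept
  as `method="stability"` with its degeneracy documented and unit-tested.
  Clusters under 5 genes become unassigned; module IDs are ordered by size.
- **Enrichment pruning.** One-sided hypergeometric over-representation per
  module × gene set against the network gene universe, BH across all pairs;
  module genes outside every significant set are dropped, and modules falling
  under 5 genes are removed. This reproduces the pruning semantics of
  GO-based filtering without a GO-DAG dependency; the synthetic gene-set
  generator provides pathway collections aligned with the planted modules.

## Subtype classifier

Features are per-module **medians** of gene-standardised expression: genes
are z-scored (training cohort statistics are frozen into the model), and the
median over a module's available genes tolerates partial panel coverage.
Modules under 50% gene coverage are flagged and their scores imputed with the
training median at prediction time; prediction requires ≥ 80% of modules to
meet coverage. By default new cohorts are standardised with the *training*
statistics (assumes a comparable scale — appropriate for same-platform data
and for detecting cohort-wide activation such as the post-treatment stromal
shift, which per-cohort standardisation would cancel); `standardise="cohort"`
switches to the cohort's own statistics for cross-platform inputs.

The ensemble is XGBoost with multiclass softmax, depth-3 trees, 200 rounds,
learning rate 0.1, single-threaded for bit-reproducibility. Stratified 5-fold
cross-validation records per-fold accuracy and one-vs-rest ROC AUC before the
final refit on all samples. Models serialise to a single JSON archive
(metadata plus booster dump) and round-trip to identical predictions.

## Survival and treatment shift

Kaplan–Meier and the k-group log-rank test are implemented from their
defining formulas (they are the package's prognosis surface and are pinned to
brute-force oracles and cross-checked against lifelines in the tests).
Conventions: subjects censored exactly at an event time remain at risk for
that time (events processed first); the log-rank statistic uses the
multivariate hypergeometric variance with a pseudoinverse on the first k − 1
groups, referred to χ²(k−1). Stage imputation: a recorded overall stage
passes through; otherwise N > 0 with M = 0 yields stage 3, anything else
stays missing. Transition tables count pre→post subtype moves over matched
pairs and report the fraction of pairs landing in each post-treatment
subtype.

## Problem sizes and numerical choices

The default study conditions are 180 samples × 2000 genes with 12 planted
modules — the scale the acceptance experiments run at. Unit and property
tests use compact cohorts (90 samples × 600 genes, 6 modules) chosen so each
stage retains enough signal to exercise its contract; at 90 samples the
|ρ|⁶ adjacency needs a baseline correlation of ~0.4 for reliable module
recovery, so the small-scale recovery tests set that explicitly. Calibration
suites use 200 replicates (FDR, log-rank power) and 500 (log-rank null).
Numerical conventions: strict inequality at the connectivity cutoff;
silhouette of singleton clusters is 0; constant genes get p = 1 and are
flagged; correlation ties in quantile normalisation average the reference
values of tied ranks; argmax ties in prediction resolve to the first class in
sorted order; all seeds fan out from one global seed by fixed offsets.

## Known limitations

- The deltaK elbow rule, while validated on planted k ∈ {2, 3, 4}, is a
  heuristic; near-balanced hierarchical structure (e.g. 2 strong groups each
  with 2 weak subgroups) can legitimately support either answer.
- Consensus clustering's optimism on null data (above) is inherited from the
  method itself.
- The location–scale batch correction assumes batch effects are per-gene
  location/scale only; interaction effects (batch × subtype) are neither
  simulated nor corrected.
- Module medians discard within-module heterogeneity; a module whose genes
  split into up- and down-regulated halves would be poorly summarised.
- Cross-platform deployment relies on the gene-standardisation choice; with
  `standardise="training"` the input must share the training scale, with
  `"cohort"` uniform cohort-wide signals are removed. This trade-off is
  fundamental to single-cohort standardisation, not specific to the
  implementation.
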