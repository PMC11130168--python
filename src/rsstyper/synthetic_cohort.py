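"""Synthetic expression cohorts with planted modules, subtypes and survival.

The generator emulates the structure of merged, log2-summarised microarray
cohorts: block-correlated gene modules (a latent-factor model, one factor per
module), a small number of planted transcriptional subtypes that shift module
means, additive and multiplicative per-batch gene-wise batch effects,
exponential subtype-dependent survival with uniform censoring, and matched
pre/post-treatment sample pairs whose post samples gain expression in
"stromal" modules (the mesenchymal-shift phenomenon seen after neoadjuvant
chemoradiotherapy).

Model for gene g in sample s:

    x_gs = mu_g + a_{g,b(s)} + c_{g,b(s)} * (w_{m(g)} f_{m(g),s}
             + delta_{m(g),t(s)} + e_gs)

with module factor f ~ N(0,1) per (module, sample), loading w solved so that
the baseline (zero-effect) within-module correlation matches
``within_module_cor_target``,
subtype shifts delta taken from ``subtype_effects``, batch offsets
a ~ N(0, batch_shift_sd^2), batch scalings c = exp(N(0, batch_scale_sd^2)) and
noise e ~ N(0, noise_sd^2). Background genes (module label 0) carry no factor
and no subtype shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneModuleSet

__all__ = [
    "CohortConfig",
    "expected_within_correlation",
    "CohortTruth",
    "generate_cohort",
    "generate_treatment_pairs",
    "generate_gene_sets",
    "write_gmt",
]

DEFAULT_MODULE_SIZES = (120, 100, 90, 80, 70, 60, 50, 45, 40, 30, 25, 20)


@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort.

    Defaults mirror the training-cohort scale the pipeline is designed around:
    180 samples, 2000 genes, 12 modules of 20-120 genes, 3 subtypes with a
    1.0 log2 module-mean shift each, 4 batches. Hazards are per-month event
    rates per subtype (subtype 1, the stromal/mesenchymal-like group, has the
    worst prognosis); censoring is uniform on (0, censor_window] months.
    """

    n_samples: int = 180
    n_genes: int = 2000
    module_sizes: tuple[int, ...] = DEFAULT_MODULE_SIZES
    n_subtypes: int = 3
    subtype_effect: float = 1.0
    subtype_effects: np.ndarray | None = None  # module x subtype log2 shifts
    within_module_cor_target: float = 0.25
    n_batches: int = 4
    batch_shift_sd: float = 0.5
    batch_scale_sd: float = 0.1
    noise_sd: float = 0.5
    hazards: tuple[float, ...] = (0.02, 0.05, 0.03)  # events / month
    censor_window: float = 120.0  # months
    stromal_subtype: int = 1
    stromal_modules: tuple[int, ...] | None = None  # 1-based module indices
    shift_effect: float = 1.5  # log2 shift on stromal modules post-treatment
    seed: int = 0

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def resolved_effects(self) -> np.ndarray:
        """The module x subtype shift matrix, building the round-robin default.

        By default module m (0-based) shifts subtype ``m % n_subtypes`` up by
        ``subtype_effect`` log2 units, so every subtype owns roughly a third of
        the modules.
        """
        if self.subtype_effects is not None:
            eff = np.asarray(self.subtype_effects, dtype=float)
            if eff.shape != (self.n_modules, self.n_subtypes):
                raise ValueError(
                    f"subtype_effects must be {self.n_modules} x {self.n_subtypes}, "
                    f"got {eff.shape}"
                )
            return eff
        eff = np.zeros((self.n_modules, self.n_subtypes))
        for m in range(self.n_modules):
            eff[m, m % self.n_subtypes] = self.subtype_effect
        return eff

    def resolved_stromal_modules(self) -> tuple[int, ...]:
        """1-based indices of the stromal modules (default: those whose largest
        planted shift belongs to ``stromal_subtype``)."""
        if self.stromal_modules is not None:
            return tuple(self.stromal_modules)
        eff = self.resolved_effects()
        out = [
            m + 1
            for m in range(self.n_modules)
            if eff[m].any() and int(np.argmax(eff[m])) == self.stromal_subtype
        ]
        return tuple(out)

    def validate(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError(
                f"module_sizes sum to {sum(self.module_sizes)} > n_genes={self.n_genes}"
            )
        if any(s <= 0 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if not 0 < self.within_module_cor_target < 1:
            raise ValueError("within_module_cor_target must lie in (0, 1)")
        for name in ("batch_shift_sd", "batch_scale_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.hazards) != self.n_subtypes:
            raise ValueError("hazards must list one rate per subtype")
        if any(h <= 0 for h in self.hazards):
            raise ValueError("hazards must be > 0")
        if self.n_batches < 1 or self.n_subtypes < 2:
            raise ValueError("need >= 1 batch and >= 2 subtypes")
        if not 0 <= self.stromal_subtype < self.n_subtypes:
            raise ValueError("stromal_subtype out of range")
        self.resolved_effects()


@dataclass
class CohortTruth:
    """Ground truth for a generated cohort.

    ``true_module`` labels genes with 1-based module indices, 0 = background.
    ``pre_post_pairs`` maps pre-treatment sample id to its post-treatment mate
    (empty for plain cohorts).
    """

    true_subtype: pd.Series
    true_module: pd.Series
    batch: pd.Series
    pre_post_pairs: dict[str, str] = field(default_factory=dict)

    def module_set(self) -> GeneModuleSet:
        modules: dict[str, list[str]] = {}
        for gene, m in self.true_module.items():
            if m > 0:
                modules.setdefault(f"M{m}", []).append(gene)
        unassigned = [g for g, m in self.true_module.items() if m == 0]
        return GeneModuleSet(modules, unassigned, {"source": "planted"})

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        sdf = pd.DataFrame(
            {"true_subtype": self.true_subtype, "batch": self.batch}
        )
        sdf.index.name = "sample_id"
        sdf["post_sample"] = [self.pre_post_pairs.get(s, "") for s in sdf.index]
        sdf.to_csv(path)
        gdf = pd.DataFrame({"true_module": self.true_module})
        gdf.index.name = "gene_id"
        gdf.to_csv(path.with_suffix(".genes.csv"))


def _balanced_labels(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    labels = np.repeat(np.arange(k), math.ceil(n / k))[:n]
    rng.shuffle(labels)
    return labels


def _architecture(config: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    """Gene-level architecture shared by every cohort drawn at one seed.

    The gene -> module placement and baseline means mu_g describe the measured
    biology, so they are fixed per seed: a classifier trained on one cohort
    can meaningfully score a second cohort (e.g. treatment pairs) generated
    with the same seed. Per-cohort quantities (batch offsets, factors, noise,
    survival) come from separate sample streams.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0)))
    module_of_gene = np.zeros(config.n_genes, dtype=int)
    placement = rng.permutation(config.n_genes)
    pos = 0
    for m, size in enumerate(config.module_sizes):
        module_of_gene[placement[pos : pos + size]] = m + 1
        pos += size
    mu = rng.normal(7.0, 1.5, size=config.n_genes)
    return module_of_gene, mu


def _module_loadings(config: CohortConfig) -> np.ndarray:
    """Factor loading hitting the baseline within-module correlation target.

    Two genes of module m share the factor term w f; everything else
    (measurement noise and the per-gene batch offsets) is independent between
    genes, so in the absence of subtype effects the within-module correlation
    is w^2 / (w^2 + noise^2 + v_batch), with v_batch the variance contributed
    by balanced batch offsets. The loading is solved from
    ``within_module_cor_target`` under that zero-effect baseline and is
    deliberately independent of the planted subtype effects: module identity
    (co-regulation strength) stays constant while the subtype contrast is
    dialled, and planted shifts inflate the realised pooled correlation above
    the baseline (see :func:`expected_within_correlation`).
    """
    rho = config.within_module_cor_target
    v_batch = (1.0 - 1.0 / config.n_batches) * config.batch_shift_sd**2
    w = math.sqrt(rho / (1.0 - rho) * (config.noise_sd**2 + v_batch))
    return np.full(config.n_modules, w)


def expected_within_correlation(config: CohortConfig) -> np.ndarray:
    """Model-implied pooled within-module Pearson correlation per module.

    (w^2 + v_m) / (w^2 + v_m + noise^2 + v_batch) where v_m is the
    across-sample variance of the module's subtype shift under balanced
    subtype proportions. Equals ``within_module_cor_target`` when the
    module carries no subtype effect; planted shifts push it above the
    baseline. Spearman measurements run a few percent below these Pearson
    values for Gaussian data.
    """
    eff = config.resolved_effects()
    p = np.full(config.n_subtypes, 1.0 / config.n_subtypes)
    v = eff**2 @ p - (eff @ p) ** 2
    w2 = _module_loadings(config) ** 2
    v_batch = (1.0 - 1.0 / config.n_batches) * config.batch_shift_sd**2
    return (w2 + v) / (w2 + v + config.noise_sd**2 + v_batch)


def _simulate_values(
    config: CohortConfig,
    rng: np.random.Generator,
    subtype: np.ndarray,
    batch: np.ndarray,
    module_of_gene: np.ndarray,
    mu: np.ndarray,
    batch_shift: np.ndarray,
    batch_scale: np.ndarray,
) -> np.ndarray:
    n_genes, n_samples = len(mu), len(subtype)
    eff = config.resolved_effects()
    w = _module_loadings(config)
    signal = rng.normal(0.0, config.noise_sd, size=(n_genes, n_samples))
    factors = rng.standard_normal((config.n_modules, n_samples))
    for m in range(config.n_modules):
        rows = module_of_gene == (m + 1)
        signal[rows] += w[m] * factors[m] + eff[m, subtype]
    return mu[:, None] + batch_shift[:, batch] + batch_scale[:, batch] * signal


def _survival(
    config: CohortConfig, rng: np.random.Generator, subtype: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    rates = np.asarray(config.hazards)[subtype]
    event_time = rng.exponential(1.0 / rates)
    censor_time = rng.uniform(0.0, config.censor_window, size=len(subtype))
    censor_time = np.maximum(censor_time, 1e-6)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return time, event


def _annotation(
    sample_ids: list[str],
    batch_names: np.ndarray,
    subtype: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    rng: np.random.Generator,
    treatment: str | list[str] = "naive",
    pair_id: list[str] | None = None,
) -> pd.DataFrame:
    n = len(sample_ids)
    # TNM fields: loosely realistic, with some overall stages masked so the
    # downstream stage-imputation rule has work to do
    t_stage = rng.integers(1, 5, size=n)
    n_stage = rng.integers(0, 3, size=n)
    m_stage = (rng.random(n) < 0.1).astype(int)
    stage = np.where(m_stage > 0, 4, np.where(n_stage > 0, 3, np.minimum(t_stage, 2)))
    stage = stage.astype(object)
    stage[rng.random(n) < 0.25] = pd.NA
    ann = pd.DataFrame(
        {
            "batch": batch_names,
            "tissue": "rectum",
            "treatment": treatment,
            "T": t_stage,
            "N": n_stage,
            "M": m_stage,
            "stage": stage,
            "time_months": np.round(time, 3),
            "event": event,
            "pair_id": pair_id if pair_id is not None else "",
            "subtype": subtype,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ann


def generate_cohort(
    config: CohortConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, CohortTruth]:
    """Simulate one cohort; deterministic for a fixed ``config.seed``.

    Returns the expression matrix, a per-sample annotation table (batch,
    tissue, treatment, TNM stage fields, follow-up time and event, pair key)
    and the ground truth (subtype, module and batch labels).
    """
    config.validate()
    module_of_gene, mu = _architecture(config)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))

    gene_ids = [f"G{i:04d}" for i in range(config.n_genes)]
    sample_ids = [f"S{i:04d}" for i in range(config.n_samples)]

    subtype = _balanced_labels(config.n_samples, config.n_subtypes, rng)
    batch = _balanced_labels(config.n_samples, config.n_batches, rng)
    batch_shift = rng.normal(0.0, config.batch_shift_sd, (config.n_genes, config.n_batches))
    batch_scale = np.exp(
        rng.normal(0.0, config.batch_scale_sd, (config.n_genes, config.n_batches))
    )

    values = _simulate_values(
        config, rng, subtype, batch, module_of_gene, mu, batch_shift, batch_scale
    )
    time, event = _survival(config, rng, subtype)

    batch_names = np.array([f"batch{b}" for b in batch])
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        pd.Series(batch_names, index=sample_ids),
    )
    ann = _annotation(sample_ids, batch_names, subtype, time, event, rng)
    truth = CohortTruth(
        true_subtype=pd.Series(subtype, index=sample_ids, name="true_subtype"),
        true_module=pd.Series(module_of_gene, index=gene_ids, name="true_module"),
        batch=expr.batch.copy(),
    )
    return expr, ann, truth


def generate_treatment_pairs(
    config: CohortConfig, n_pairs: int
) -> tuple[ExpressionMatrix, pd.DataFrame, CohortTruth]:
    """Simulate matched pre/post-treatment sample pairs.

    Post samples equal their pre mates plus ``config.shift_effect`` log2 units
    on every stromal-module gene plus fresh measurement noise, modelling the
    stromal activation observed after neoadjuvant treatment. Both members of a
    pair share a batch. The gene architecture (module placement, baseline
    means) is shared with :func:`generate_cohort` at the same seed, so a
    model trained on that cohort can classify these pairs.
    """
    config.validate()
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    stromal = config.resolved_stromal_modules()
    if not stromal:
        raise ValueError("config designates no stromal modules")
    module_of_gene, mu = _architecture(config)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))

    gene_ids = [f"G{i:04d}" for i in range(config.n_genes)]

    subtype = _balanced_labels(n_pairs, config.n_subtypes, rng)
    batch = _balanced_labels(n_pairs, config.n_batches, rng)
    batch_shift = rng.normal(0.0, config.batch_shift_sd, (config.n_genes, config.n_batches))
    batch_scale = np.exp(
        rng.normal(0.0, config.batch_scale_sd, (config.n_genes, config.n_batches))
    )

    pre = _simulate_values(
        config, rng, subtype, batch, module_of_gene, mu, batch_shift, batch_scale
    )
    stromal_rows = np.isin(module_of_gene, list(stromal))
    post = pre + rng.normal(0.0, config.noise_sd, size=pre.shape)
    post[stromal_rows] += config.shift_effect

    pre_ids = [f"P{i:04d}_pre" for i in range(n_pairs)]
    post_ids = [f"P{i:04d}_post" for i in range(n_pairs)]
    pair_keys = [f"pair{i:04d}" for i in range(n_pairs)]
    sample_ids = pre_ids + post_ids
    values = pd.DataFrame(
        np.hstack([pre, post]), index=gene_ids, columns=sample_ids
    )
    batch_names = np.array([f"batch{b}" for b in batch])
    batches = pd.Series(
        np.concatenate([batch_names, batch_names]), index=sample_ids
    )
    expr = ExpressionMatrix(values, batches)

    time, event = _survival(config, rng, subtype)
    ann_pre = _annotation(
        pre_ids, batch_names, subtype, time, event, rng, "pre", pair_keys
    )
    ann_post = _annotation(
        post_ids, batch_names, subtype, time, event, rng, "post", pair_keys
    )
    ann = pd.concat([ann_pre, ann_post])

    truth = CohortTruth(
        true_subtype=pd.Series(
            np.concatenate([subtype, subtype]), index=sample_ids, name="true_subtype"
        ),
        true_module=pd.Series(module_of_gene, index=gene_ids, name="true_module"),
        batch=batches.copy(),
        pre_post_pairs=dict(zip(pre_ids, post_ids)),
    )
    return expr, ann, truth


def generate_gene_sets(
    truth: CohortTruth,
    n_random_sets: int = 20,
    coverage: float = 0.8,
    set_size: int = 40,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Synthetic gene-set collection aligned with the planted modules.

    One "pathway" per planted module containing ``coverage`` of its genes plus
    random background padding, and ``n_random_sets`` unrelated random sets, so
    hypergeometric enrichment pruning has genuine structure to find.
    """
    rng = np.random.default_rng(seed)
    genes = np.array(truth.true_module.index)
    sets: dict[str, list[str]] = {}
    for m in sorted(truth.true_module.unique()):
        if m == 0:
            continue
        members = genes[truth.true_module.to_numpy() == m]
        take = max(1, int(round(coverage * len(members))))
        core = rng.choice(members, size=take, replace=False)
        pad = rng.choice(genes, size=max(0, set_size - take), replace=False)
        sets[f"PATHWAY_M{m}"] = sorted(set(core) | set(pad))
    for i in range(n_random_sets):
        sets[f"RANDOM_{i:02d}"] = sorted(
            rng.choice(genes, size=set_size, replace=False)
        )
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path: str | Path) -> None:
    """Write gene sets in GMT format (name, description, tab-joined genes)."""
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, "synthetic", *genes]) + "\n")
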