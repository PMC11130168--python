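"""Merging multi-study expression cohorts: deduplication, quantile
normalisation, and location-scale batch correction.

The merge path assumes each study arrives as an already log2-summarised
genes x samples matrix. Duplicated samples (the same array submitted under
different accessions) are detected either by file checksum or by near-perfect
expression correlation; merged studies are intersected on gene identifiers
and batch-corrected gene-wise.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .datatypes import ExpressionMatrix

__all__ = [
    "DuplicateReport",
    "detect_duplicates",
    "drop_duplicates",
    "quantile_normalise",
    "correct_batch",
    "merge_studies",
]


@dataclass
class DuplicateReport:
    """Groups of samples deemed duplicates and the representative kept.

    ``groups`` are disjoint sets of sample (or file) identifiers; ``kept``
    holds the lexicographically smallest member of each group. ``method`` is
    ``"checksum"`` or ``"correlation"``.
    """

    groups: list[set[str]]
    kept: list[str]
    method: str

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.groups:
            if seen & g:
                raise ValueError("duplicate groups must be disjoint")
            seen |= g
        if not set(self.kept) <= seen:
            raise ValueError("kept must be members of the groups")

    @property
    def to_drop(self) -> set[str]:
        drop: set[str] = set()
        for g, k in zip(self.groups, self.kept):
            drop |= g - {k}
        return drop


def _group_by_components(ids: list[str], adjacency: np.ndarray) -> DuplicateReport:
    n_comp, labels = connected_components(csr_matrix(adjacency), directed=False)
    groups: list[set[str]] = []
    kept: list[str] = []
    for c in range(n_comp):
        members = {ids[i] for i in np.flatnonzero(labels == c)}
        if len(members) > 1:
            groups.append(members)
            kept.append(min(members))
    order = np.argsort([min(g) for g in groups]) if groups else []
    return DuplicateReport(
        [groups[i] for i in order], [kept[i] for i in order], method=""
    )


def detect_duplicates(
    source: list[str | Path] | ExpressionMatrix,
    method: str = "correlation",
    cor_threshold: float = 0.999,
) -> DuplicateReport:
    """Find duplicated samples by md5 checksum of raw files or by correlation.

    Checksum mode groups byte-identical files. Correlation mode groups samples
    whose pairwise Pearson correlation is >= ``cor_threshold`` (default 0.999),
    taking the transitive closure; one representative per group — the
    lexicographically smallest identifier — is kept.
    """
    if method == "checksum":
        if isinstance(source, ExpressionMatrix):
            raise TypeError("checksum mode requires a list of file paths")
        paths = [Path(p) for p in source]
        digests: dict[str, list[str]] = {}
        for p in paths:
            try:
                digest = hashlib.md5(p.read_bytes()).hexdigest()
            except OSError as err:
                raise IOError(f"cannot read file {p}") from err
            digests.setdefault(digest, []).append(str(p))
        groups = [set(v) for v in digests.values() if len(v) > 1]
        groups.sort(key=min)
        report = DuplicateReport(groups, [min(g) for g in groups], "checksum")
        return report
    if method == "correlation":
        if not isinstance(source, ExpressionMatrix):
            raise TypeError("correlation mode requires an ExpressionMatrix")
        ids = list(source.sample_ids)
        if len(ids) < 2:
            return DuplicateReport([], [], "correlation")
        r = np.corrcoef(source.values.to_numpy(), rowvar=False)
        adj = (r >= cor_threshold) & ~np.eye(len(ids), dtype=bool)
        report = _group_by_components(ids, adj)
        report.method = "correlation"
        return report
    raise ValueError(f"unknown duplicate-detection method: {method!r}")


def drop_duplicates(m: ExpressionMatrix, report: DuplicateReport) -> ExpressionMatrix:
    """Remove all but the kept representative of each duplicate group."""
    keep = [s for s in m.sample_ids if s not in report.to_drop]
    return m.subset_samples(keep)


def quantile_normalise(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean distribution of order statistics.

    After normalisation each column's sorted values equal the across-sample
    mean of sorted columns; tied values within a column receive the mean of
    the reference values at their tied ranks. Within-column rank order is
    preserved. Idempotent.
    """
    if m.n_samples < 2:
        raise ValueError("quantile normalisation needs at least 2 samples")
    x = m.values.to_numpy(dtype=float)
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        ranks = pd.Series(x[:, j]).rank(method="average").to_numpy()  # 1-based
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (reference[lo] + reference[hi])
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.gene_ids, columns=m.sample_ids), m.batch.copy()
    )


def correct_batch(
    m: ExpressionMatrix, allow_single_batch: bool = False
) -> ExpressionMatrix:
    """Per-gene location-scale batch adjustment to the pooled distribution.

    Each batch's values for a gene are centred and rescaled so the batch mean
    and standard deviation match the gene's pooled (cross-batch) mean and
    standard deviation; genes with zero variance inside a batch are centred
    only. This is a ComBat-style adjustment without empirical-Bayes shrinkage,
    which suffices for additive/multiplicative batch structure and is exactly
    reproducible.
    """
    batches = m.batch.unique()
    if len(batches) < 2:
        if allow_single_batch:
            return m.copy()
        raise ValueError("batch correction needs >= 2 batches")
    counts = m.batch.value_counts()
    small = counts[counts < 3]
    if len(small):
        raise ValueError(
            f"batches with fewer than 3 samples: {sorted(small.index.tolist())}"
        )
    x = m.values.to_numpy(dtype=float)
    pooled_mean = x.mean(axis=1)
    pooled_sd = x.std(axis=1, ddof=1)
    out = np.empty_like(x)
    batch_arr = m.batch.to_numpy()
    for b in batches:
        cols = batch_arr == b
        xb = x[:, cols]
        mu_b = xb.mean(axis=1)
        sd_b = xb.std(axis=1, ddof=1)
        scale = np.ones_like(sd_b)
        ok = (sd_b > 0) & (pooled_sd > 0)
        scale[ok] = pooled_sd[ok] / sd_b[ok]
        out[:, cols] = (xb - mu_b[:, None]) * scale[:, None] + pooled_mean[:, None]
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.gene_ids, columns=m.sample_ids), m.batch.copy()
    )


def merge_studies(
    matrices: list[ExpressionMatrix],
    study_names: list[str] | None = None,
    min_genes: int = 100,
) -> ExpressionMatrix:
    """Concatenate studies on the intersection of their gene identifiers.

    The batch label of every sample becomes its source study name. Raises if
    the gene intersection falls below ``min_genes`` or if sample identifiers
    collide across studies (callers must deduplicate or rename first).
    """
    if len(matrices) < 2:
        raise ValueError("merge needs at least 2 studies")
    if study_names is None:
        study_names = [f"study{i}" for i in range(len(matrices))]
    if len(study_names) != len(matrices):
        raise ValueError("one study name per matrix required")

    common = matrices[0].gene_ids
    for m in matrices[1:]:
        common = common.intersection(m.gene_ids)
    if len(common) < min_genes:
        raise ValueError(
            f"gene intersection has {len(common)} genes (< {min_genes})"
        )
    common = common.sort_values()

    all_ids: list[str] = []
    for m in matrices:
        all_ids.extend(m.sample_ids)
    dupes = pd.Index(all_ids)[pd.Index(all_ids).duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate sample identifiers across studies: {dupes[:5]}")

    blocks = [m.values.loc[common] for m in matrices]
    values = pd.concat(blocks, axis=1)
    batch = pd.Series(
        np.repeat(study_names, [m.n_samples for m in matrices]), index=values.columns
    )
    return ExpressionMatrix(values, batch)
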