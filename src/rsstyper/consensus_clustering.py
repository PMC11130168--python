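"""Unsupervised subtype discovery by consensus resampling.

Samples are compared with a 1 - Spearman correlation distance over genes,
clustered agglomeratively, and stabilised by Monti-style consensus
resampling: repeated subsampling, re-clustering, and tallying how often each
sample pair lands in the same cluster. The number of clusters is chosen from
the relative increase of the area under the consensus CDF ("deltaK"), made
algorithmic with a drop-fraction elbow rule since the original selection is
visual. Silhouette widths and PCA coordinates serve as diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples

from .datatypes import ExpressionMatrix

__all__ = [
    "ConsensusResult",
    "spearman_distance",
    "hierarchical_labels",
    "consensus_matrix",
    "consensus_sweep",
    "delta_k_select",
    "silhouette_widths",
    "pca_coordinates",
]


def spearman_distance(m: ExpressionMatrix) -> np.ndarray:
    """Pairwise 1 - Spearman correlation between sample profiles."""
    ranks = rankdata(m.values.to_numpy(), axis=0)
    r = np.corrcoef(ranks, rowvar=False)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)


def _check_distance(dist: np.ndarray) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dist), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    return 0.5 * (dist + dist.T)


def hierarchical_labels(
    dist: np.ndarray, linkage: str = "average", k: int = 2
) -> np.ndarray:
    """Agglomerative clustering of a distance matrix cut at ``k`` clusters.

    Returns 0-based labels; merge-height ties are resolved by scipy's
    deterministic smallest-pair ordering.
    """
    dist = _check_distance(dist)
    n = dist.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must lie in [2, {n}], got {k}")
    if linkage not in {"average", "complete", "ward"}:
        raise ValueError(f"unsupported linkage: {linkage!r}")
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    return hierarchy.fcluster(Z, t=k, criterion="maxclust") - 1


def consensus_matrix(
    m: ExpressionMatrix | np.ndarray,
    k: int,
    n_resamples: int = 100,
    sample_frac: float = 0.8,
    seed: int | np.random.SeedSequence = 0,
    linkage: str = "average",
) -> tuple[np.ndarray, np.ndarray]:
    """Monti consensus matrix for one candidate cluster count.

    Entry (i, j) is the fraction of resamples in which samples i and j were
    assigned to the same cluster, among resamples where both were drawn.
    Returns ``(consensus, co_drawn)`` where ``co_drawn`` counts how often each
    pair was drawn together; pairs never drawn together have consensus 0 and
    ``co_drawn`` 0. Deterministic under a fixed seed.

    Accepts either an expression matrix (distance = 1 - Spearman over genes)
    or a precomputed symmetric distance matrix.
    """
    if n_resamples < 2:
        raise ValueError("n_resamples must be >= 2")
    if not 0 < sample_frac <= 1:
        raise ValueError("sample_frac must lie in (0, 1]")
    dist = spearman_distance(m) if isinstance(m, ExpressionMatrix) else _check_distance(m)
    n = dist.shape[0]
    sub_n = max(2, int(round(sample_frac * n)))
    if k > sub_n:
        raise ValueError(f"k={k} exceeds subsample size {sub_n}")
    rng = np.random.default_rng(seed)
    together = np.zeros((n, n))
    co_drawn = np.zeros((n, n))
    for _ in range(n_resamples):
        idx = np.sort(rng.choice(n, size=sub_n, replace=False))
        labels = hierarchical_labels(dist[np.ix_(idx, idx)], linkage, k)
        drawn = np.zeros(n, dtype=bool)
        drawn[idx] = True
        co_drawn += np.outer(drawn, drawn)
        same = labels[:, None] == labels[None, :]
        together[np.ix_(idx, idx)] += same
    with np.errstate(invalid="ignore"):
        consensus = np.where(co_drawn > 0, together / np.maximum(co_drawn, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    return consensus, co_drawn


def consensus_sweep(
    m: ExpressionMatrix | np.ndarray,
    k_range=range(2, 9),
    n_resamples: int = 100,
    sample_frac: float = 0.8,
    seed: int = 0,
    linkage: str = "average",
) -> dict[int, np.ndarray]:
    """Consensus matrices for every k in ``k_range`` (fresh resamples per k)."""
    dist = spearman_distance(m) if isinstance(m, ExpressionMatrix) else _check_distance(m)
    out: dict[int, np.ndarray] = {}
    for k in k_range:
        out[k] = consensus_matrix(
            dist, k, n_resamples, sample_frac, np.random.SeedSequence((seed, k)), linkage
        )[0]
    return out


@dataclass
class ConsensusResult:
    """Consensus matrices over a k range with the deltaK selection."""

    k_range: list[int]
    consensus: dict[int, np.ndarray]
    area: dict[int, float]
    delta_k: dict[int, float]
    k_selected: int
    labels: dict[int, np.ndarray]
    low_confidence: bool = False

    def delta_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_range,
                "area": [self.area[k] for k in self.k_range],
                "delta": [self.delta_k[k] for k in self.k_range],
            }
        )


def consensus_cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of the upper-triangle consensus values."""
    vals = np.sort(consensus[np.triu_indices_from(consensus, k=1)])
    m = len(vals)
    xs = np.concatenate([[0.0], vals, [1.0]])
    cdf = np.concatenate([[np.mean(vals <= 0.0)], np.arange(1, m + 1) / m, [1.0]])
    return float(np.trapezoid(cdf, xs))


def delta_k_select(
    consensus_by_k: dict[int, np.ndarray],
    drop_frac: float = 0.5,
    labels_linkage: str = "ward",
    min_delta: float = 0.1,
    rel_delta: float = 0.15,
    low_confidence_delta: float = 0.1,
) -> ConsensusResult:
    """Choose the cluster count from the deltaK curve.

    delta(2) = A(2) and delta(k) = (A(k) - A(k-1)) / A(k-1) for k > 2, with
    A(k) the consensus CDF area. The visual elbow is operationalised as the
    LARGEST k whose relative area gain is non-negligible — at least
    ``min_delta`` absolutely and ``rel_delta`` of the largest gain at k >= 3
    — and whose successor collapses below ``drop_frac * delta(k)``; without
    any such k the argmax of delta is used. The relative floor matters
    because splitting a true cluster still inflates the consensus CDF area
    somewhat, so a fixed threshold alone cannot separate the last informative
    k from the first redundant one across effect sizes.

    When every delta at k >= 3 stays under ``low_confidence_delta`` the
    result is flagged low-confidence (near-uniform consensus). Final labels
    per k come from hierarchical clustering of 1 - consensus; Ward linkage by
    default, which resists the outlier chaining that average linkage suffers
    on fuzzy consensus matrices (a lone atypical sample would otherwise claim
    a whole cluster at the cut).
    """
    ks = sorted(consensus_by_k)
    if len(ks) < 3:
        raise ValueError("need at least 3 candidate cluster counts")
    if ks[0] != 2 or ks != list(range(2, ks[-1] + 1)):
        raise ValueError("k range must be contiguous and start at 2")

    area = {k: consensus_cdf_area(consensus_by_k[k]) for k in ks}
    delta: dict[int, float] = {2: area[2]}
    for k in ks[1:]:
        delta[k] = (area[k] - area[k - 1]) / area[k - 1] if area[k - 1] > 0 else 0.0

    floor = max(min_delta, rel_delta * max(delta[k] for k in ks[1:]))
    candidates = [
        k
        for k in ks[:-1]
        if delta[k] >= floor and delta[k + 1] < drop_frac * delta[k]
    ]
    k_selected = max(candidates) if candidates else max(ks, key=lambda k: delta[k])
    low_confidence = max(delta[k] for k in ks[1:]) < low_confidence_delta

    labels: dict[int, np.ndarray] = {}
    for k in ks:
        d = 1.0 - consensus_by_k[k]
        np.fill_diagonal(d, 0.0)
        labels[k] = hierarchical_labels(
            np.clip(0.5 * (d + d.T), 0.0, None), labels_linkage, k
        )

    return ConsensusResult(
        k_range=ks,
        consensus=dict(consensus_by_k),
        area=area,
        delta_k=delta,
        k_selected=k_selected,
        labels=labels,
        low_confidence=low_confidence,
    )


def silhouette_widths(
    dist: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, pd.Series]:
    """Per-sample silhouette widths on a precomputed distance matrix.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a the mean intra-cluster
    distance and b the smallest mean distance to another cluster; singleton
    clusters get width 0. Returns the widths and per-cluster mean widths.
    """
    dist = _check_distance(dist)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    widths = silhouette_samples(dist, labels, metric="precomputed")
    per_cluster = pd.Series(
        {c: float(widths[labels == c].mean()) for c in uniq}, name="mean_width"
    )
    return widths, per_cluster


def pca_coordinates(m: ExpressionMatrix, n_components: int = 2) -> pd.DataFrame:
    """Thin diagnostic export: sample PCA coordinates on centred genes."""
    x = m.values.to_numpy().T  # samples x genes
    coords = PCA(n_components=n_components, random_state=0).fit_transform(
        x - x.mean(axis=0)
    )
    return pd.DataFrame(
        coords,
        index=m.sample_ids,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
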