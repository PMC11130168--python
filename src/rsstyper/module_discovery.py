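"""Gene-module discovery from subtype-labelled expression.

The chain follows the weighted co-expression playbook: keep genes that are
differential between any pair of subtypes (FDR-controlled), build an unsigned
power adjacency from Spearman similarities, optionally restrict to
high-connectivity (hub-like) genes, convert to topological-overlap
dissimilarity, cluster the gene dendrogram over a sweep of cut sizes, and
prune modules by gene-set over-representation, dropping modules that fall
under a minimum size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform
from scipy.stats import f as f_dist
from scipy.stats import hypergeom, rankdata
from sklearn.metrics import silhouette_samples
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, GeneModuleSet

__all__ = [
    "NetworkMatrices",
    "two_group_diff",
    "select_subtype_genes",
    "build_network",
    "restrict_by_connectivity",
    "tom_dissimilarity",
    "tree_cut_modules",
    "enrichment_prune",
    "read_gmt",
]


# ---------------------------------------------------------------------------
# Differential expression filter
# ---------------------------------------------------------------------------

def two_group_diff(
    m: ExpressionMatrix, groups, fdr_alpha: float = 0.05
) -> pd.DataFrame:
    """Per-gene one-way ANOVA between two groups with BH adjustment.

    ``groups`` is a per-sample label vector with exactly two levels. For two
    groups the F statistic equals the squared pooled two-sided t. Returns a
    DataFrame indexed by gene with columns ``statistic`` (F), ``p``, ``q``
    (BH-adjusted over all tested genes), ``log2fc`` (first-level mean minus
    second-level mean; data are log2 scale) and ``constant`` (genes flat
    across all samples, assigned p = 1 by convention).
    """
    groups = pd.Series(np.asarray(groups), index=m.sample_ids)
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"exactly 2 group levels required, got {levels}")
    a = m.values.loc[:, groups == levels[0]].to_numpy()
    b = m.values.loc[:, groups == levels[1]].to_numpy()
    n1, n2 = a.shape[1], b.shape[1]
    if min(n1, n2) < 2:
        raise ValueError("both groups need at least 2 samples")

    mean1, mean2 = a.mean(axis=1), b.mean(axis=1)
    var1, var2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * var1 + (n2 - 1) * var2) / (n1 + n2 - 2)
    diff = mean1 - mean2
    denom = sp2 * (1.0 / n1 + 1.0 / n2)

    constant = (np.abs(diff) < 1e-300) & (sp2 <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, diff**2 / denom, np.inf)
    stat = np.where(constant, 0.0, stat)
    p = np.where(
        constant, 1.0, f_dist.sf(stat, 1, n1 + n2 - 2)
    )
    p = np.where(np.isinf(stat), 0.0, p)
    q = multipletests(p, alpha=fdr_alpha, method="fdr_bh")[1]
    return pd.DataFrame(
        {"statistic": stat, "p": p, "q": q, "log2fc": diff, "constant": constant},
        index=m.gene_ids,
    )


def select_subtype_genes(
    m: ExpressionMatrix,
    labels,
    fdr_alpha: float = 0.05,
    adjust: str = "pooled",
) -> list[str]:
    """Genes differential in any pairwise subtype comparison at FDR < alpha.

    Every pair of subtype labels is tested gene-wise; a gene is selected when
    its adjusted q falls under ``fdr_alpha`` in at least one pair (union
    semantics). With ``adjust="pooled"`` (default) BH runs once across all
    pairwise tests, which keeps the false-discovery rate of the union at the
    nominal level; ``adjust="per_pair"`` adjusts each comparison separately.
    """
    labels = pd.Series(np.asarray(labels), index=m.sample_ids)
    counts = labels.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"subtypes with fewer than 2 samples: {sorted(small.index)}")
    levels = sorted(counts.index)
    if len(levels) < 2:
        raise ValueError("need at least 2 distinct subtype labels")
    if adjust not in {"pooled", "per_pair"}:
        raise ValueError(f"unknown adjust mode: {adjust!r}")

    raw_p: list[np.ndarray] = []
    selected = np.zeros(m.n_genes, dtype=bool)
    for la, lb in combinations(levels, 2):
        pair_mask = labels.isin([la, lb]).to_numpy()
        sub = m.subset_samples(m.sample_ids[pair_mask])
        res = two_group_diff(sub, labels[pair_mask].to_numpy(), fdr_alpha)
        if adjust == "per_pair":
            selected |= (res["q"] < fdr_alpha).to_numpy()
        else:
            raw_p.append(res["p"].to_numpy())
    if adjust == "pooled":
        q = multipletests(np.concatenate(raw_p), alpha=fdr_alpha, method="fdr_bh")[1]
        selected = (q.reshape(len(raw_p), m.n_genes) < fdr_alpha).any(axis=0)
    return [g for g, s in zip(m.gene_ids, selected) if s]


# ---------------------------------------------------------------------------
# Co-expression network
# ---------------------------------------------------------------------------

@dataclass
class NetworkMatrices:
    """Similarity, power adjacency and normalised connectivity of a network.

    ``similarity`` holds Spearman correlations (genes x genes), ``adjacency``
    is ``|similarity| ** beta`` with a unit diagonal, and ``connectivity`` is
    the per-gene mean adjacency to all other genes, so it lies in [0, 1].
    """

    similarity: pd.DataFrame
    adjacency: pd.DataFrame
    connectivity: pd.Series
    beta: float

    @property
    def gene_ids(self) -> pd.Index:
        return self.adjacency.index


def _scale_free_r2(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """R^2 and slope of log10 p(k) vs log10 k over connectivity bins."""
    k = connectivity[connectivity > 0]
    if len(k) < n_bins:
        return 0.0, 0.0
    edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 3:
        return 0.0, 0.0
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, len(edges) - 2)
    centers, freqs = [], []
    for b in range(len(edges) - 1):
        members = k[idx == b]
        if len(members):
            centers.append(members.mean())
            freqs.append(len(members) / len(k))
    if len(centers) < 3:
        return 0.0, 0.0
    x = np.log10(centers)
    y = np.log10(freqs)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
    return float(r2), float(slope)


def build_network(
    m: ExpressionMatrix, beta: float | None = 6, groups=None
) -> NetworkMatrices:
    """Spearman similarity -> unsigned power adjacency ``|r| ** beta``.

    Genes without variance are dropped with a warning before correlating.
    With ``beta=None`` the smallest power in 1..10 whose connectivity
    distribution fits a scale-free law with R^2 >= 0.8 (negative slope) is
    chosen; if none qualifies the conventional beta = 6 is used.

    When per-sample ``groups`` (e.g. subtype labels) are given, each gene is
    centred on its group means before correlating. Genes selected for
    between-group differences are otherwise correlated merely for sharing a
    group contrast, which smears distinct co-regulated modules together;
    centring makes module membership reflect co-regulation proper, however
    large the group effect.
    """
    if m.n_genes < 2:
        raise ValueError("network needs at least 2 genes")
    if m.n_samples < 4:
        raise ValueError("network needs at least 4 samples")
    x = m.values.to_numpy()
    if groups is not None:
        groups = np.asarray(groups)
        if len(groups) != m.n_samples:
            raise ValueError("groups must label every sample")
        x = x.copy()
        for g in pd.unique(groups):
            cols = groups == g
            x[:, cols] -= x[:, cols].mean(axis=1, keepdims=True)
    variable = x.std(axis=1) > 0
    if not variable.all():
        dropped = [g for g, v in zip(m.gene_ids, variable) if not v]
        warnings.warn(
            f"dropping {len(dropped)} zero-variance genes: {dropped[:5]}",
            stacklevel=2,
        )
        x = x[variable]
    genes = m.gene_ids[variable]
    if len(genes) < 2:
        raise ValueError("fewer than 2 variable genes")

    ranks = rankdata(x, axis=1)
    s = np.corrcoef(ranks)
    np.fill_diagonal(s, 1.0)
    s = np.clip(s, -1.0, 1.0)

    def adjacency_for(b: float) -> tuple[np.ndarray, np.ndarray]:
        a = np.abs(s) ** b
        np.fill_diagonal(a, 1.0)
        k = (a.sum(axis=1) - 1.0) / (len(genes) - 1)
        return a, k

    if beta is None:
        beta = 6.0
        for cand in range(1, 11):
            _, k = adjacency_for(cand)
            r2, slope = _scale_free_r2(k)
            if r2 >= 0.8 and slope < 0:
                beta = float(cand)
                break
    a, k = adjacency_for(beta)
    return NetworkMatrices(
        similarity=pd.DataFrame(s, index=genes, columns=genes),
        adjacency=pd.DataFrame(a, index=genes, columns=genes),
        connectivity=pd.Series(k, index=genes, name="connectivity"),
        beta=float(beta),
    )


def restrict_by_connectivity(
    net: NetworkMatrices, cutoff: str | float = "median"
) -> NetworkMatrices:
    """Keep genes whose connectivity strictly exceeds the cutoff.

    ``cutoff="median"`` (default) uses the median connectivity over genes;
    a float applies an explicit threshold. Matrices are re-sliced to the
    surviving genes; connectivity values are carried over, not recomputed.
    """
    if len(net.gene_ids) < 4:
        raise ValueError("restriction needs at least 4 genes")
    value = float(net.connectivity.median()) if cutoff == "median" else float(cutoff)
    keep = net.connectivity > value
    kept = net.gene_ids[keep.to_numpy()]
    if len(kept) < 2:
        raise ValueError(
            f"connectivity cutoff {value:.4g} leaves {len(kept)} genes (< 2)"
        )
    return NetworkMatrices(
        similarity=net.similarity.loc[kept, kept],
        adjacency=net.adjacency.loc[kept, kept],
        connectivity=net.connectivity.loc[kept],
        beta=net.beta,
    )


def tom_dissimilarity(net: NetworkMatrices | pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Topological-overlap dissimilarity D = 1 - TOM of an adjacency matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(K_i, K_j) + 1 - a_ij) for i != j,
    where K_i is the unnormalised adjacency row sum excluding the diagonal,
    and TOM_ii = 1. Entries lie in [0, 1].
    """
    if isinstance(net, NetworkMatrices):
        adj = net.adjacency
    elif isinstance(net, pd.DataFrame):
        adj = net
    else:
        arr = np.asarray(net, dtype=float)
        adj = pd.DataFrame(
            arr,
            index=[f"g{i}" for i in range(arr.shape[0])],
            columns=[f"g{i}" for i in range(arr.shape[0])],
        )
    a = adj.to_numpy(dtype=float).copy()
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    np.fill_diagonal(a, 0.0)
    row_sum = a.sum(axis=1)  # K_i
    shared = a @ a
    numer = shared + a
    denom = np.minimum.outer(row_sum, row_sum) + 1.0 - a
    assert (denom > 0).all(), "TOM denominator must stay positive for a in [0,1]"
    tom = numer / denom
    np.fill_diagonal(tom, 1.0)
    d = np.clip(1.0 - tom, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=adj.index, columns=adj.columns)


# ---------------------------------------------------------------------------
# Tree-cut module detection
# ---------------------------------------------------------------------------

def _components_from_threshold(
    freq: np.ndarray, stability_frac: float
) -> np.ndarray:
    adj = freq >= stability_frac
    np.fill_diagonal(adj, False)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    return labels


def tree_cut_modules(
    D: pd.DataFrame | np.ndarray,
    k_min: int = 5,
    k_max: int = 101,
    min_size: int = 5,
    method: str = "best_k",
    stability_frac: float = 0.8,
    gene_ids=None,
    linkage: str = "average",
) -> GeneModuleSet:
    """Cut the gene dendrogram on TOM dissimilarity into modules.

    An average-linkage dendrogram on ``D`` is cut at every k in
    ``[k_min, k_max]``. With the default ``method="best_k"`` the partition
    with the highest mean silhouette width on ``D`` is kept — since cuts of a
    single dendrogram are nested, any co-membership summary over the sweep is
    itself equivalent to one cut, so the sweep is resolved by choosing the
    internally best-supported cut. ``method="stability"`` instead links gene
    pairs co-assigned in at least ``stability_frac`` of cuts and takes
    connected components.

    Clusters smaller than ``min_size`` end up unassigned. Module IDs are
    ``M1, M2, ...`` in decreasing size order.
    """
    if isinstance(D, pd.DataFrame):
        ids = list(D.index)
        d = D.to_numpy(dtype=float)
    else:
        d = np.asarray(D, dtype=float)
        ids = list(gene_ids) if gene_ids is not None else [f"g{i}" for i in range(len(d))]
    n = d.shape[0]
    if not 2 <= k_min <= k_max:
        raise ValueError("need 2 <= k_min <= k_max")
    if k_max >= n:
        raise ValueError(f"k_max={k_max} must be smaller than the gene count {n}")
    if method not in {"best_k", "stability"}:
        raise ValueError(f"unknown tree-cut method: {method!r}")

    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    Z = hierarchy.linkage(squareform(d, checks=False), method=linkage)
    cuts = {
        k: hierarchy.fcluster(Z, t=k, criterion="maxclust") for k in range(k_min, k_max + 1)
    }

    if method == "best_k":
        best_score, best_labels = -np.inf, None
        for k in sorted(cuts):
            labels = cuts[k]
            if len(np.unique(labels)) < 2:
                continue
            score = float(silhouette_samples(d, labels, metric="precomputed").mean())
            if score > best_score + 1e-12:
                best_score, best_labels = score, labels
        if best_labels is None:
            raise ValueError("no cut produced more than one cluster")
        labels = best_labels
    else:
        freq = np.zeros((n, n))
        for labels_k in cuts.values():
            freq += labels_k[:, None] == labels_k[None, :]
        freq /= len(cuts)
        labels = _components_from_threshold(freq, stability_frac)

    clusters: dict[int, list[str]] = {}
    for gene, lab in zip(ids, labels):
        clusters.setdefault(int(lab), []).append(gene)
    keep = [genes for genes in clusters.values() if len(genes) >= min_size]
    unassigned = sorted(
        g for genes in clusters.values() if len(genes) < min_size for g in genes
    )
    if not keep:
        hint = (
            "lower stability_frac" if method == "stability" else "lower min_size"
        )
        raise ValueError(f"no module of size >= {min_size} found; {hint}")
    keep.sort(key=lambda genes: (-len(genes), genes[0]))
    modules = {f"M{i + 1}": sorted(genes) for i, genes in enumerate(keep)}
    return GeneModuleSet(
        modules,
        unassigned,
        provenance={
            "method": method,
            "k_min": k_min,
            "k_max": k_max,
            "min_size": min_size,
            "stability_frac": stability_frac,
            "linkage": linkage,
        },
    )


# ---------------------------------------------------------------------------
# Enrichment pruning
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection into name -> gene-list form."""
    import gseapy

    return gseapy.read_gmt(str(path))


def enrichment_prune(
    modules: GeneModuleSet,
    gene_sets: dict[str, list[str]],
    alpha: float = 0.05,
    min_size: int = 5,
    universe: list[str] | None = None,
) -> GeneModuleSet:
    """Drop module genes without significant gene-set support.

    Each module x gene-set pair is scored with a one-sided hypergeometric
    over-representation test against the network gene universe, BH-adjusted
    across all pairs. Within each module only genes belonging to at least one
    significant set survive; modules shrinking below ``min_size`` are removed
    entirely. Gene-set members absent from the universe are ignored with a
    warning.
    """
    if not gene_sets:
        raise ValueError("gene_sets must be non-empty")
    if universe is None:
        universe = modules.all_genes() + list(modules.unassigned)
    universe_set = set(universe)
    N = len(universe_set)

    trimmed: dict[str, set[str]] = {}
    missing = 0
    for name, genes in gene_sets.items():
        inside = set(genes) & universe_set
        missing += len(set(genes)) - len(inside)
        if inside:
            trimmed[name] = inside
    if missing:
        warnings.warn(
            f"{missing} gene-set members are outside the universe and were ignored",
            stacklevel=2,
        )

    pairs: list[tuple[str, str]] = []
    pvals: list[float] = []
    for mid in modules.module_ids:
        mod_genes = set(modules.modules[mid])
        for name, sgenes in trimmed.items():
            overlap = len(mod_genes & sgenes)
            # P(X >= overlap) drawing |module| from N with |set| successes
            pvals.append(
                float(hypergeom.sf(overlap - 1, N, len(sgenes), len(mod_genes)))
            )
            pairs.append((mid, name))
    reject = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    significant: dict[str, set[str]] = {}
    for (mid, name), rej in zip(pairs, reject):
        if rej:
            significant.setdefault(mid, set()).update(trimmed[name])

    new_modules: dict[str, list[str]] = {}
    unassigned = set(modules.unassigned)
    for mid in modules.module_ids:
        supported = sorted(set(modules.modules[mid]) & significant.get(mid, set()))
        dropped = set(modules.modules[mid]) - set(supported)
        if len(supported) >= min_size:
            new_modules[mid] = supported
            unassigned |= dropped
        else:
            unassigned |= set(modules.modules[mid])
    provenance = dict(modules.provenance)
    provenance.update({"enrichment_alpha": alpha, "enrichment_min_size": min_size})
    return GeneModuleSet(new_modules, sorted(unassigned), provenance)
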