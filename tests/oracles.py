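"""Independent brute-force reference implementations.

Deliberately naive (double/triple loops, direct summation) so they share no
code path with the package; used to pin the numerical operations to their
defining formulas.
"""

from __future__ import annotations

import math

import numpy as np


def bh_adjust(p):
    """Benjamini-Hochberg step-up adjusted p-values, literal definition."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return np.array(q)


def silhouette_brute(dist, labels):
    """Per-sample silhouette widths by explicit double loop."""
    dist = np.asarray(dist, float)
    labels = np.asarray(labels)
    n = len(labels)
    widths = np.zeros(n)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            widths[i] = 0.0
            continue
        a = sum(dist[i, j] for j in own) / len(own)
        b = math.inf
        for c in set(labels) - {labels[i]}:
            other = [j for j in range(n) if labels[j] == c]
            b = min(b, sum(dist[i, j] for j in other) / len(other))
        widths[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return widths


def tom_brute(adj):
    """Topological-overlap dissimilarity via triple loop."""
    a = np.asarray(adj, float).copy()
    n = a.shape[0]
    np.fill_diagonal(a, 0.0)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            k_i = sum(a[i, u] for u in range(n) if u != i)
            k_j = sum(a[j, u] for u in range(n) if u != j)
            tom = (shared + a[i, j]) / (min(k_i, k_j) + 1.0 - a[i, j])
            d[i, j] = 1.0 - tom
    return d


def km_brute(time, event):
    """Product-limit estimate recomputed from scratch at each event time."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    out = []
    for t in sorted(set(time[event == 1])):
        surv = 1.0
        for s in sorted(set(time[event == 1])):
            if s > t:
                break
            at_risk = int(np.sum(time >= s))
            d = int(np.sum((time == s) & (event == 1)))
            surv *= 1.0 - d / at_risk
        out.append((t, surv))
    return out


def logrank_brute(time, event, group):
    """Two-or-more-group log-rank statistic from longhand O/E/V sums."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    levels = sorted(set(group))
    k = len(levels)
    o_minus_e = np.zeros(k)
    V = np.zeros((k, k))
    for t in sorted(set(time[event == 1])):
        n = int(np.sum(time >= t))
        d = int(np.sum((time == t) & (event == 1)))
        n_g = np.array([np.sum((time >= t) & (group == lv)) for lv in levels], float)
        d_g = np.array(
            [np.sum((time == t) & (event == 1) & (group == lv)) for lv in levels],
            float,
        )
        e_g = n_g * d / n
        o_minus_e += d_g - e_g
        if n > 1:
            for a in range(k):
                for b in range(k):
                    if a == b:
                        V[a, b] += (
                            d * (n - d) / (n - 1) * n_g[a] * (n - n_g[a]) / n**2
                        )
                    else:
                        V[a, b] -= d * (n - d) / (n - 1) * n_g[a] * n_g[b] / n**2
    z = o_minus_e[: k - 1]
    v = V[: k - 1, : k - 1]
    stat = float(z @ np.linalg.pinv(v) @ z) if np.any(z) else 0.0
    return stat


def hypergeom_tail(N, K, n, k):
    """P(X >= k) for overlap of an n-draw with K successes in N, by summation."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
    return total


def average_linkage_brute(dist, k):
    """Naive agglomerative average-linkage clustering cut at k clusters.

    Scans all cluster pairs each step; ties in merge height break on the
    smallest pair index, matching scipy's deterministic ordering.
    """
    dist = np.asarray(dist, float)
    n = dist.shape[0]
    clusters = [[i] for i in range(n)]
    while len(clusters) > k:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.zeros(n, int)
    for c, members in enumerate(clusters):
        for i in members:
            labels[i] = c
    return labels
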