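"""Differential filter, co-expression network, TOM, tree cut, enrichment."""

import numpy as np
import pandas as pd
import pytest

from rsstyper import (
    ExpressionMatrix,
    GeneModuleSet,
    NetworkMatrices,
    build_network,
    enrichment_prune,
    generate_cohort,
    read_gmt,
    restrict_by_connectivity,
    select_subtype_genes,
    tom_dissimilarity,
    tree_cut_modules,
    two_group_diff,
    write_gmt,
)
from rsstyper.synthetic_cohort import CohortConfig

from oracles import bh_adjust, hypergeom_tail, tom_brute


def expr_from(values, prefix="S"):
    values = np.asarray(values, float)
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"G{i:03d}" for i in range(values.shape[0])],
            columns=[f"{prefix}{j}" for j in range(values.shape[1])],
        )
    )


class TestTwoGroupDiff:
    def test_flat_genes_are_flagged_not_significant(self):
        m = expr_from(np.ones((20, 10)))
        res = two_group_diff(m, ["a"] * 5 + ["b"] * 5)
        assert res["constant"].all()
        assert (res["p"] == 1.0).all()

    def test_planted_shift_is_detected_among_nulls(self, rng):
        """One 2.0 log2 shift (sd 0.5, 20 vs 20) among 999 null genes clears
        BH at 5% essentially always."""
        hits = 0
        for rep in range(10):
            x = rng.normal(0, 0.5, size=(1000, 40))
            x[0, 20:] += 2.0
            res = two_group_diff(expr_from(x), ["a"] * 20 + ["b"] * 20)
            hits += res["q"].iloc[0] < 0.05
        assert hits == 10

    def test_bh_adjustment_matches_step_up_oracle(self, rng):
        x = rng.normal(size=(50, 16))
        res = two_group_diff(expr_from(x), ["a"] * 8 + ["b"] * 8)
        assert np.allclose(res["q"], bh_adjust(res["p"]), atol=1e-12)
        # frozen hand example of the step-up procedure itself
        assert np.allclose(
            bh_adjust([0.001, 0.01, 0.02, 0.9]), [0.004, 0.02, 0.0267, 0.9], atol=1e-4
        )

    def test_log2_fold_change_is_group_mean_difference(self, rng):
        x = rng.normal(size=(30, 12))
        groups = ["a"] * 6 + ["b"] * 6
        res = two_group_diff(expr_from(x), groups)
        manual = x[:, :6].mean(axis=1) - x[:, 6:].mean(axis=1)
        assert np.allclose(res["log2fc"], manual)


class TestSelectSubtypeGenes:
    def test_union_over_pairs_matches_manual_pooling(self, rng):
        x = rng.normal(size=(60, 30))
        x[:5, 10:20] += 2.0  # genes 0-4 separate group b from a and c
        labels = np.array(["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        m = expr_from(x)
        got = select_subtype_genes(m, labels, 0.05, adjust="pooled")

        from statsmodels.stats.multitest import multipletests

        ps = []
        for la, lb in [("a", "b"), ("a", "c"), ("b", "c")]:
            mask = np.isin(labels, [la, lb])
            sub = m.subset_samples(m.sample_ids[mask])
            ps.append(two_group_diff(sub, labels[mask])["p"].to_numpy())
        q = multipletests(np.concatenate(ps), method="fdr_bh")[1].reshape(3, -1)
        manual = [g for g, s in zip(m.gene_ids, (q < 0.05).any(axis=0)) if s]
        assert got == manual
        assert set(got) >= {"G000", "G001", "G002", "G003", "G004"}

    def test_most_shifted_module_genes_selected(self, small_cohort):
        _, expr, _, truth = small_cohort
        sel = select_subtype_genes(expr, truth.true_subtype.to_numpy())
        tm = truth.true_module
        assert (tm.loc[sel] > 0).sum() / (tm > 0).sum() >= 0.9

    def test_small_subtype_is_rejected(self, rng):
        m = expr_from(rng.normal(size=(10, 5)))
        with pytest.raises(ValueError, match="fewer than 2"):
            select_subtype_genes(m, ["a", "a", "b", "b", "c"])


class TestBuildNetwork:
    def test_perfect_correlation_gives_unit_adjacency(self):
        base = np.linspace(0, 1, 12)
        m = expr_from(np.stack([base, 2 * base + 3]))
        for beta in (1, 2, 6):
            net = build_network(m, beta)
            assert net.adjacency.iloc[0, 1] == pytest.approx(1.0)

    def test_adjacency_is_powered_absolute_similarity(self, rng):
        m = expr_from(rng.normal(size=(15, 20)))
        net = build_network(m, beta=2)
        off = ~np.eye(15, dtype=bool)
        assert np.allclose(
            net.adjacency.to_numpy()[off],
            np.abs(net.similarity.to_numpy()[off]) ** 2,
        )

    def test_connectivity_is_mean_offdiagonal_adjacency(self, rng):
        m = expr_from(rng.normal(size=(10, 25)))
        net = build_network(m, beta=6)
        a = net.adjacency.to_numpy()
        manual = (a.sum(axis=1) - 1.0) / 9
        assert np.allclose(net.connectivity, manual)
        assert (net.connectivity >= 0).all() and (net.connectivity <= 1).all()

    def test_zero_variance_genes_dropped_with_warning(self, rng):
        x = rng.normal(size=(8, 10))
        x[3] = 5.0
        with pytest.warns(UserWarning, match="zero-variance"):
            net = build_network(expr_from(x), 6)
        assert "G003" not in net.gene_ids

    def test_group_centring_removes_contrast_driven_correlation(self, rng):
        """Two gene blocks shifted in the same subtype correlate pooled but
        not once group means are centred out."""
        groups = np.array(["a"] * 20 + ["b"] * 20)
        x = rng.normal(0, 0.3, size=(20, 40))
        x[:, groups == "b"] += 2.0  # all genes share the same group contrast
        pooled = build_network(expr_from(x), beta=1)
        centred = build_network(expr_from(x), beta=1, groups=groups)
        off = ~np.eye(20, dtype=bool)
        assert np.abs(pooled.similarity.to_numpy()[off]).mean() > 0.6
        assert np.abs(centred.similarity.to_numpy()[off]).mean() < 0.2


class TestRestrictByConnectivity:
    @staticmethod
    def net_with_connectivity(k):
        n = len(k)
        ids = [f"G{i}" for i in range(n)]
        eye = pd.DataFrame(np.eye(n), index=ids, columns=ids)
        return NetworkMatrices(
            similarity=eye,
            adjacency=eye,
            connectivity=pd.Series(k, index=ids),
            beta=6,
        )

    def test_median_cutoff_is_strict(self):
        net = self.net_with_connectivity([0.05, 0.1, 0.2, 0.3])
        kept = restrict_by_connectivity(net, "median")  # median = 0.15
        assert list(kept.gene_ids) == ["G2", "G3"]

    def test_explicit_cutoff_keeps_high_connectivity_genes(self):
        net = self.net_with_connectivity([0.05, 0.1, 0.2, 0.3])
        kept = restrict_by_connectivity(net, 0.1)
        assert list(kept.gene_ids) == ["G2", "G3"]

    def test_all_equal_connectivity_errors(self):
        # strict > with median cutoff removes every gene
        net = self.net_with_connectivity([0.2, 0.2, 0.2, 0.2])
        with pytest.raises(ValueError, match="leaves 0 genes"):
            restrict_by_connectivity(net, "median")


class TestTomDissimilarity:
    def test_two_gene_network_uses_row_sums(self):
        # K_i = 0.8 for both genes, so TOM = 0.8 / (0.8 + 1 - 0.8) = 0.8
        d = tom_dissimilarity(np.array([[1.0, 0.8], [0.8, 1.0]]))
        assert d.iloc[0, 1] == pytest.approx(0.2, abs=1e-12)

    def test_identical_fully_connected_rows_have_zero_dissimilarity(self):
        a = np.ones((3, 3))
        d = tom_dissimilarity(a)
        assert np.allclose(d.to_numpy(), 0.0)

    def test_matches_triple_loop_oracle(self, rng):
        for trial in range(5):
            a = rng.uniform(0, 1, size=(6, 6))
            a = 0.5 * (a + a.T)
            np.fill_diagonal(a, 1.0)
            d = tom_dissimilarity(a).to_numpy()
            assert np.allclose(d, tom_brute(a), atol=1e-12)

    def test_range_and_permutation_equivariance(self, rng):
        a = rng.uniform(0, 1, size=(10, 10))
        a = 0.5 * (a + a.T)
        np.fill_diagonal(a, 1.0)
        d = tom_dissimilarity(a).to_numpy()
        assert d.min() >= 0.0 and d.max() <= 1.0
        perm = rng.permutation(10)
        d_perm = tom_dissimilarity(a[np.ix_(perm, perm)]).to_numpy()
        assert np.allclose(d_perm, d[np.ix_(perm, perm)], atol=1e-12)


def block_dissimilarity(sizes, within=0.2, between=0.95, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    d = np.where(labels[:, None] == labels[None, :], within, between)
    d += rng.uniform(0, 0.02, size=d.shape)
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    ids = [f"G{i:03d}" for i in range(len(labels))]
    return pd.DataFrame(d, index=ids, columns=ids), labels


class TestTreeCutModules:
    def test_two_clean_blocks_recovered(self):
        D, labels = block_dissimilarity([10, 10])
        ms = tree_cut_modules(D, k_min=2, k_max=10, min_size=5)
        assert ms.n_modules == 2
        assert sorted(len(v) for v in ms.modules.values()) == [10, 10]

    def test_stability_graph_equals_quantile_cut(self):
        """Cuts of one dendrogram are nested, so thresholding co-membership
        frequency reproduces a single cut of the sweep (the construction's
        degeneracy, kept as an explicit contract)."""
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import squareform

        D, _ = block_dissimilarity([12, 10, 8], seed=4)
        ms = tree_cut_modules(
            D, k_min=2, k_max=3, min_size=2, method="stability", stability_frac=1.0
        )
        # frac 1.0 -> pairs together in every cut -> partition at k_max
        Z = hierarchy.linkage(
            squareform(D.to_numpy(), checks=False), method="average"
        )
        direct = hierarchy.fcluster(Z, t=3, criterion="maxclust")
        sizes = sorted(len(v) for v in ms.modules.values())
        assert sizes == sorted(np.bincount(direct)[1:].tolist())

    def test_small_cluster_lands_unassigned(self):
        D, _ = block_dissimilarity([12, 10, 4])
        ms = tree_cut_modules(D, k_min=2, k_max=12, min_size=5)
        assert ms.n_modules == 2
        assert len(ms.unassigned) == 4

    def test_module_ids_ordered_by_size(self):
        D, _ = block_dissimilarity([8, 14, 11])
        ms = tree_cut_modules(D, k_min=2, k_max=12, min_size=5)
        sizes = [len(ms.modules[mid]) for mid in ms.module_ids]
        assert sizes == sorted(sizes, reverse=True) == [14, 11, 8]

    def test_planted_modules_recovered_from_cohort(self):
        """Compact cohort sized so module co-regulation survives the power
        adjacency at 90 samples (baseline correlation 0.4)."""
        from rsstyper.preprocessing import correct_batch, quantile_normalise

        cfg = CohortConfig(
            seed=11,
            n_samples=90,
            n_genes=600,
            module_sizes=(50, 45, 40, 35, 30, 25),
            n_batches=3,
            within_module_cor_target=0.4,
        )
        expr, _, truth = generate_cohort(cfg)
        expr = correct_batch(quantile_normalise(expr))
        labels = truth.true_subtype.to_numpy()
        genes = select_subtype_genes(expr, labels)
        net = build_network(expr.subset_genes(genes), 6, groups=labels)
        D = tom_dissimilarity(net)
        ms = tree_cut_modules(D, 5, min(101, len(D) - 1), 5)
        tm = truth.true_module
        for m in sorted(set(tm) - {0}):
            planted = set(tm.index[tm == m])
            best = max(
                len(planted & set(g)) / len(planted | set(g))
                for g in ms.modules.values()
            )
            assert best >= 0.7

    def test_k_max_must_stay_under_gene_count(self):
        D, _ = block_dissimilarity([6, 6])
        with pytest.raises(ValueError, match="k_max"):
            tree_cut_modules(D, k_min=2, k_max=12, min_size=3)


class TestEnrichmentPrune:
    def test_perfectly_enriched_module_is_retained(self, rng):
        genes = [f"G{i:03d}" for i in range(100)]
        modules = GeneModuleSet({"M1": genes[:10]}, genes[10:])
        pruned = enrichment_prune(modules, {"SET": genes[:10]}, 0.05, 5)
        assert pruned.modules["M1"] == sorted(genes[:10])

    def test_hypergeometric_tail_matches_direct_summation(self):
        from scipy.stats import hypergeom

        # module of 10 from universe 100, set of 10, overlap 5
        assert hypergeom.sf(4, 100, 10, 10) == pytest.approx(
            hypergeom_tail(100, 10, 10, 5), abs=1e-12
        )

    def test_module_shrinking_below_minimum_is_dropped(self):
        genes = [f"G{i:03d}" for i in range(60)]
        modules = GeneModuleSet({"M1": genes[:6]}, genes[6:])
        # the only significant set covers 4 of the 6 module genes
        pruned = enrichment_prune(modules, {"SET": genes[:4]}, 0.05, 5)
        assert pruned.n_modules == 0
        assert set(pruned.unassigned) == set(genes)

    def test_unknown_gene_set_members_warn(self):
        genes = [f"G{i:03d}" for i in range(30)]
        modules = GeneModuleSet({"M1": genes[:8]}, genes[8:])
        with pytest.warns(UserWarning, match="outside the universe"):
            enrichment_prune(modules, {"SET": genes[:8] + ["XXX"]}, 0.05, 5)

    def test_gmt_round_trip(self, tmp_path):
        sets = {"A": ["G1", "G2", "G3"], "B": ["G2", "G9"]}
        write_gmt(sets, tmp_path / "sets.gmt")
        assert read_gmt(tmp_path / "sets.gmt") == sets


def test_module_recovery_monotone_in_effect_size():
    """Planted-module recovery never degrades as the subtype effect grows."""
    from rsstyper.preprocessing import correct_batch, quantile_normalise

    means = []
    for eff in (0.5, 1.0, 2.0):
        vals = []
        for seed in (1, 2, 3):
            cfg = CohortConfig(
                seed=seed,
                subtype_effect=eff,
                n_samples=90,
                n_genes=600,
                module_sizes=(50, 45, 40, 35, 30, 25),
                n_batches=3,
                within_module_cor_target=0.4,
            )
            expr, _, truth = generate_cohort(cfg)
            expr = correct_batch(quantile_normalise(expr))
            labels = truth.true_subtype.to_numpy()
            genes = select_subtype_genes(expr, labels)
            net = build_network(expr.subset_genes(genes), 6, groups=labels)
            ms = tree_cut_modules(
                tom_dissimilarity(net), 5, min(101, len(net.gene_ids) - 1), 5
            )
            tm = truth.true_module
            jac = [
                max(
                    len(set(tm.index[tm == m]) & set(g))
                    / len(set(tm.index[tm == m]) | set(g))
                    for g in ms.modules.values()
                )
                for m in sorted(set(tm) - {0})
            ]
            vals.append(np.mean(jac))
        means.append(np.mean(vals))
    assert means[1] >= means[0] - 0.05
    assert means[2] >= means[1] - 0.05
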