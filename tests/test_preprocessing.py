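"""Deduplication, quantile normalisation, batch correction, study merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from rsstyper import (
    ExpressionMatrix,
    correct_batch,
    detect_duplicates,
    drop_duplicates,
    generate_cohort,
    merge_studies,
    quantile_normalise,
)
from rsstyper.synthetic_cohort import CohortConfig


def make_matrix(values, batch=None, prefix="S"):
    values = np.asarray(values, float)
    df = pd.DataFrame(
        values,
        index=[f"G{i}" for i in range(values.shape[0])],
        columns=[f"{prefix}{j}" for j in range(values.shape[1])],
    )
    b = None if batch is None else pd.Series(batch, index=df.columns)
    return ExpressionMatrix(df, b)


class TestDetectDuplicates:
    def test_checksum_groups_byte_identical_files(self, tmp_path):
        (tmp_path / "a.cel").write_bytes(b"payload-1")
        (tmp_path / "b.cel").write_bytes(b"payload-1")
        (tmp_path / "c.cel").write_bytes(b"payload-2")
        report = detect_duplicates(sorted(tmp_path.iterdir()), "checksum")
        assert len(report.groups) == 1 and len(report.groups[0]) == 2
        assert report.kept == [str(tmp_path / "a.cel")]

    def test_checksum_unreadable_file_names_it(self, tmp_path):
        with pytest.raises(IOError, match="missing.cel"):
            detect_duplicates([tmp_path / "missing.cel"], "checksum")

    def test_correlation_groups_a_duplicated_column(self, rng):
        x = rng.normal(size=(50, 5))
        x = np.hstack([x, x[:, [2]]])  # S5 duplicates S2
        report = detect_duplicates(make_matrix(x), "correlation")
        assert report.groups == [{"S2", "S5"}]
        assert report.kept == ["S2"]
        kept = drop_duplicates(make_matrix(x), report)
        assert "S5" not in kept.sample_ids

    def test_independent_noise_yields_no_groups(self, rng):
        x = rng.normal(size=(80, 10))
        report = detect_duplicates(make_matrix(x), "correlation")
        assert report.groups == []

    def test_grouping_is_order_invariant_and_idempotent(self, rng):
        x = rng.normal(size=(40, 4))
        x = np.hstack([x, x[:, [0]], x[:, [0]]])
        m = make_matrix(x)
        report = detect_duplicates(m, "correlation")
        perm = list(reversed(list(m.sample_ids)))
        report_perm = detect_duplicates(m.subset_samples(perm), "correlation")
        assert report.groups == report_perm.groups
        cleaned = drop_duplicates(m, report)
        report2 = detect_duplicates(cleaned, "correlation")
        assert report2.groups == []


class TestQuantileNormalise:
    def test_hand_computed_reference(self):
        m = make_matrix([[1, 4], [2, 5], [3, 6]])
        out = quantile_normalise(m).values.to_numpy()
        assert np.allclose(out, [[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])

    def test_permuted_columns_share_value_multiset(self, rng):
        base = rng.normal(size=30)
        cols = np.stack([rng.permutation(base) for _ in range(4)], axis=1)
        out = quantile_normalise(make_matrix(cols)).values.to_numpy()
        for j in range(4):
            assert np.allclose(np.sort(out[:, j]), np.sort(base))

    def test_idempotent_and_rank_preserving(self, rng):
        m = make_matrix(rng.normal(size=(40, 6)))
        once = quantile_normalise(m)
        twice = quantile_normalise(once)
        assert np.allclose(once.values, twice.values)
        for j in range(6):
            assert (
                np.argsort(once.values.iloc[:, j].to_numpy())
                == np.argsort(m.values.iloc[:, j].to_numpy())
            ).all()

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            quantile_normalise(make_matrix([[1.0], [2.0]]))

    @given(
        arrays(
            float,
            (12, 3),
            elements=st.floats(-50, 50, allow_nan=False, width=32),
            unique=True,
        )
    )
    def test_columns_become_exchangeable(self, x):
        out = quantile_normalise(make_matrix(x)).values.to_numpy()
        for j in range(1, 3):
            assert np.allclose(np.sort(out[:, 0]), np.sort(out[:, j]), atol=1e-9)


class TestCorrectBatch:
    def test_additive_offsets_are_removed(self, rng):
        x = rng.normal(size=(30, 12))
        batch = ["A"] * 6 + ["B"] * 6
        x[:, :6] += 1.0
        x[:, 6:] -= 1.0
        out = correct_batch(make_matrix(x, batch))
        v = out.values.to_numpy()
        assert np.allclose(v[:, :6].mean(axis=1), v[:, 6:].mean(axis=1), atol=1e-9)

    def test_pooled_mean_is_preserved(self, rng):
        x = rng.normal(size=(25, 15))
        batch = ["A"] * 5 + ["B"] * 5 + ["C"] * 5
        m = make_matrix(x, batch)
        out = correct_batch(m)
        assert np.allclose(
            out.values.mean(axis=1), m.values.mean(axis=1), atol=1e-9
        )

    def test_batch_variance_fraction_drops(self):
        """eta^2 (per-gene variance explained by batch) falls under 0.02."""
        cfg = CohortConfig(
            seed=8,
            n_samples=60,
            n_genes=300,
            module_sizes=(30, 25),
            batch_shift_sd=0.8,
            n_batches=3,
        )
        expr, _, _ = generate_cohort(cfg)

        def eta2(m):
            v = m.values.to_numpy()
            grand = v.mean(axis=1, keepdims=True)
            ss_tot = ((v - grand) ** 2).sum(axis=1)
            ss_b = np.zeros(v.shape[0])
            for b in m.batch.unique():
                cols = (m.batch == b).to_numpy()
                ss_b += cols.sum() * (v[:, cols].mean(axis=1) - grand[:, 0]) ** 2
            return ss_b / ss_tot

        assert np.median(eta2(expr)) > 0.1  # batch effect genuinely present
        assert np.median(eta2(correct_batch(expr))) < 0.02

    def test_single_batch_needs_override(self):
        m = make_matrix(np.random.default_rng(0).normal(size=(10, 5)))
        with pytest.raises(ValueError, match="2 batches"):
            correct_batch(m)
        assert np.allclose(
            correct_batch(m, allow_single_batch=True).values, m.values
        )

    def test_small_batch_is_named(self, rng):
        m = make_matrix(rng.normal(size=(10, 5)), ["A", "A", "A", "B", "B"])
        with pytest.raises(ValueError, match="B"):
            correct_batch(m)


class TestMergeStudies:
    def test_full_overlap_concatenates_samples(self, rng):
        a = make_matrix(rng.normal(size=(120, 4)), prefix="A")
        b = make_matrix(rng.normal(size=(120, 6)), prefix="B")
        merged = merge_studies([a, b], ["s1", "s2"])
        assert merged.n_genes == 120 and merged.n_samples == 10
        assert list(merged.batch.unique()) == ["s1", "s2"]

    def test_partial_overlap_keeps_intersection(self, rng):
        a = ExpressionMatrix(
            pd.DataFrame(
                rng.normal(size=(500, 3)),
                index=[f"G{i}" for i in range(500)],
                columns=["A0", "A1", "A2"],
            )
        )
        b = ExpressionMatrix(
            pd.DataFrame(
                rng.normal(size=(500, 3)),
                index=[f"G{i}" for i in range(200, 700)],
                columns=["B0", "B1", "B2"],
            )
        )
        merged = merge_studies([a, b])
        assert merged.n_genes == 300

    def test_disjoint_gene_sets_error(self, rng):
        a = make_matrix(rng.normal(size=(150, 3)), prefix="A")
        b = ExpressionMatrix(
            pd.DataFrame(
                rng.normal(size=(150, 3)),
                index=[f"H{i}" for i in range(150)],
                columns=["B0", "B1", "B2"],
            )
        )
        with pytest.raises(ValueError, match="intersection"):
            merge_studies([a, b])

    def test_duplicate_sample_ids_error(self, rng):
        a = make_matrix(rng.normal(size=(150, 3)))
        b = make_matrix(rng.normal(size=(150, 3)))
        with pytest.raises(ValueError, match="duplicate sample"):
            merge_studies([a, b])
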