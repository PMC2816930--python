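"""Unit and property tests for the tissue-set KS running-sum scores."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ks_2samp

from dualks import (
    ClassVector,
    DualKSError,
    ExpressionMatrix,
    ks_increments,
    running_sum,
    score_all,
    score_gene_down,
    score_gene_up,
)

from conftest import make_dataset
from oracles import ks_down_oracle, ks_up_oracle

F58 = 8.0 / 5.0  # the worked example's out-of-class decrement N/(N-N_l)


class TestIncrements:
    def test_worked_example_increment_sequence(self, worked):
        X, Y = worked
        order, _ = running_sum(X.values[0], Y, "C1", "decreasing")
        inc = ks_increments(order, Y, "C1")
        expected = [-F58, 8 / 3, -F58, 8 / 3, -F58, 8 / 3, -F58, -F58]
        np.testing.assert_allclose(inc, expected, atol=1e-12)

    def test_two_sample_increments(self):
        y = ClassVector.from_labels(["A", "B"])
        np.testing.assert_allclose(ks_increments([0, 1], y, "A"), [2.0, -2.0])

    def test_unknown_class_is_named_in_error(self, worked):
        _, Y = worked
        with pytest.raises(DualKSError, match="C9"):
            ks_increments(np.arange(8), Y, "C9")

    def test_bad_permutation_rejected(self, worked):
        _, Y = worked
        with pytest.raises(DualKSError, match="permutation"):
            ks_increments([0] * 8, Y, "C1")

    @given(
        n_a=st.integers(1, 6),
        n_b=st.integers(1, 6),
        seed=st.integers(0, 2**20),
    )
    @settings(max_examples=50, deadline=None)
    def test_increments_sum_to_zero(self, n_a, n_b, seed):
        rng = np.random.default_rng(seed)
        labels = rng.permutation(["A"] * n_a + ["B"] * n_b)
        y = ClassVector.from_labels(labels, classes=["A", "B"])
        order = rng.permutation(n_a + n_b)
        for c in ("A", "B"):
            assert abs(ks_increments(order, y, c).sum()) < 1e-9


class TestGeneScores:
    def test_worked_example_up_score_and_running_sum(self, worked):
        X, Y = worked
        assert score_gene_up(X.values[0], Y, "C1") == pytest.approx(16 / 5, abs=1e-12)
        _, sums = running_sum(X.values[0], Y, "C1", "decreasing")
        expected = [-8 / 5, 16 / 15, -8 / 15, 32 / 15, 8 / 15, 16 / 5, 8 / 5, 0.0]
        np.testing.assert_allclose(sums, expected, atol=1e-12)

    def test_worked_example_down_score_and_running_sum(self, worked):
        X, Y = worked
        assert score_gene_down(X.values[0], Y, "C1") == pytest.approx(8 / 5, abs=1e-12)
        _, sums = running_sum(X.values[0], Y, "C1", "increasing")
        expected = [-8 / 5, -16 / 5, -8 / 15, -32 / 15, 8 / 15, -16 / 15, 8 / 5, 0.0]
        np.testing.assert_allclose(sums, expected, atol=1e-12)

    def test_lone_class_sample_at_top_scores_n(self):
        y = ClassVector.from_labels(["A", "B"])
        assert score_gene_up([10.0, 1.0], y, "A") == pytest.approx(2.0)
        assert score_gene_down([10.0, 1.0], y, "A") == pytest.approx(0.0)

    def test_matches_brute_force_ecdf_oracle(self, rng):
        """u and d equal N x one-sided two-sample KS distances (dual route)."""
        for _ in range(10):
            X, Y = make_dataset(rng, n_genes=20, n_per_class=4)
            gene = X.values[rng.integers(X.n_genes)]
            for c in Y.classes:
                u = score_gene_up(gene, Y, c)
                d = score_gene_down(gene, Y, c)
                assert u == pytest.approx(ks_up_oracle(gene, Y.labels, c), abs=1e-9)
                assert d == pytest.approx(ks_down_oracle(gene, Y.labels, c), abs=1e-9)
                # independent library route for the same identity
                cls, rest = gene[Y.labels == c], gene[Y.labels != c]
                stat = ks_2samp(cls, rest, alternative="less").statistic
                assert u == pytest.approx(Y.n_samples * stat, abs=1e-9)

    def test_down_equals_minus_min_of_decreasing_running_sum(self, rng):
        X, Y = make_dataset(rng, n_genes=10, n_per_class=5, classes=("A", "B"))
        for i in range(X.n_genes):
            for c in Y.classes:
                _, sums = running_sum(X.values[i], Y, c, "decreasing")
                assert score_gene_down(X.values[i], Y, c) == pytest.approx(
                    -sums.min(), abs=1e-9
                )

    def test_score_is_n_when_class_occupies_the_top(self):
        y = ClassVector.from_labels(["A", "A", "B", "B"])
        assert score_gene_up([9.0, 8.0, 2.0, 1.0], y, "A") == pytest.approx(4.0)
        # split class: strictly below N
        assert score_gene_up([9.0, 1.0, 8.0, 2.0], y, "A") < 4.0

    def test_non_finite_expression_rejected(self, worked):
        _, Y = worked
        with pytest.raises(DualKSError, match="finite"):
            score_gene_up([np.nan] + [0.0] * 7, Y, "C1")


class TestScoreAll:
    def test_worked_example_table_entries(self, worked):
        X, Y = worked
        table = score_all(X, Y)
        assert table.up.loc["gene1", "C1"] == pytest.approx(16 / 5, abs=1e-12)
        assert table.down.loc["gene1", "C1"] == pytest.approx(8 / 5, abs=1e-12)
        assert table.up_delta.loc["gene1", "C1"] == pytest.approx(8 / 5, abs=1e-12)

    def test_matches_per_gene_scoring(self, rng):
        X, Y = make_dataset(rng, n_genes=15, n_per_class=4)
        table = score_all(X, Y)
        for i in rng.choice(X.n_genes, size=5, replace=False):
            for c in Y.classes:
                u = score_gene_up(X.values[i], Y, c, sample_ids=X.sample_ids)
                d = score_gene_down(X.values[i], Y, c, sample_ids=X.sample_ids)
                assert table.up.iloc[i][c] == pytest.approx(u, abs=1e-12)
                assert table.down.iloc[i][c] == pytest.approx(d, abs=1e-12)

    def test_deltas_are_antisymmetric(self, rng):
        X, Y = make_dataset(rng, n_genes=50, n_per_class=4)
        table = score_all(X, Y)
        np.testing.assert_allclose(
            (table.up_delta + table.down_delta).to_numpy(), 0.0, atol=1e-9
        )

    def test_constant_gene_is_deterministic(self, worked):
        _, Y = worked
        X = ExpressionMatrix(np.ones((1, 8)), ["flat"], [f"s{j}" for j in range(8)])
        t1 = score_all(X, Y)
        t2 = score_all(X, Y)
        assert t1.up.equals(t2.up) and t1.down.equals(t2.down)

    def test_sample_order_invariance(self, rng):
        X, Y = make_dataset(rng, n_genes=12, n_per_class=4)
        perm = rng.permutation(X.n_samples)
        Xp = ExpressionMatrix(X.values[:, perm], X.gene_ids, X.sample_ids[perm])
        Yp = ClassVector(Y.labels[perm], Y.classes)
        t1, t2 = score_all(X, Y), score_all(Xp, Yp)
        np.testing.assert_allclose(t1.up.to_numpy(), t2.up.to_numpy(), atol=1e-9)
        np.testing.assert_allclose(t1.down.to_numpy(), t2.down.to_numpy(), atol=1e-9)

    def test_scores_bounded_by_n(self, rng):
        X, Y = make_dataset(rng, n_genes=40, n_per_class=3)
        table = score_all(X, Y)
        n = X.n_samples
        assert (table.up.to_numpy() >= -1e-12).all() and (table.up.to_numpy() <= n + 1e-12).all()
        assert (table.down.to_numpy() >= -1e-12).all() and (table.down.to_numpy() <= n + 1e-12).all()

    def test_dimension_mismatch_rejected(self, rng, worked):
        X, _ = make_dataset(rng, n_genes=5, n_per_class=4)
        _, Y8 = worked
        with pytest.raises(DualKSError, match="does not match"):
            score_all(X, Y8)


class TestContainers:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(DualKSError, match="duplicate gene"):
            ExpressionMatrix(np.ones((2, 2)), ["g", "g"], ["a", "b"])
        with pytest.raises(DualKSError, match="duplicate sample"):
            ExpressionMatrix(np.ones((1, 2)), ["g"], ["a", "a"])

    def test_nan_rejected_at_construction(self):
        with pytest.raises(DualKSError, match="non-finite"):
            ExpressionMatrix([[1.0, np.nan]], ["g"], ["a", "b"])

    def test_single_class_rejected(self):
        with pytest.raises(DualKSError):
            ClassVector.from_labels(["A", "A", "A"])

    def test_empty_class_in_list_rejected(self):
        with pytest.raises(DualKSError, match="degenerate"):
            ClassVector.from_labels(["A", "A", "B"], classes=["A", "B", "C"])

    def test_bootstrap_subset_mangles_duplicate_sample_ids(self, rng):
        X, _ = make_dataset(rng, n_genes=3, n_per_class=2, classes=("A", "B"))
        sub = X.subset_samples([0, 0, 1])
        assert len(set(sub.sample_ids)) == 3
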