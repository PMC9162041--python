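import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from miaf import (
    build_extended_table,
    compute_weights,
    make_representation,
    parse_newick,
    relative_abundance,
)
from oracles import extended_counts_naive


class TestNewickParsing:
    def test_simple_rooted_tree(self):
        t = parse_newick("((A:1,B:2):3,C:4);")
        assert t.n_leaves == 3
        assert t.leaf_labels == ["A", "B", "C"]
        assert t.internal_nonroot().size == 1

    def test_star_multifurcation(self):
        t = parse_newick("(A:1,B:1,C:1);")
        assert t.n_leaves == 3
        assert t.internal_nonroot().size == 0

    def test_malformed_string_raises(self):
        with pytest.raises(ValueError):
            parse_newick("((A,B")

    def test_duplicate_leaf_labels_raise(self):
        with pytest.raises(ValueError):
            parse_newick("((A:1,A:1):1,B:1);")

    def test_missing_branch_length_raises_unless_opted_in(self):
        with pytest.raises(ValueError, match="branch length"):
            parse_newick("((A:1,B):1,C:1);")
        t = parse_newick("((A:1,B):1,C:1);", allow_missing_lengths=True)
        b_idx = t.leaves[t.leaf_labels.index("B")]
        assert t.branch_length[b_idx] == 0.0

    def test_explicitly_unrooted_raises(self):
        with pytest.raises(ValueError, match="unrooted"):
            parse_newick("[&U] ((A:1,B:1):1,C:1);")

    def test_negative_branch_length_raises(self):
        with pytest.raises(ValueError):
            parse_newick("((A:1,B:-2):1,C:1);")


class TestExtendedTable:
    def test_figure_tree_internal_sums(self, fig1_tree, fig1_counts):
        ext = build_extended_table(fig1_counts, fig1_tree)
        col = dict(zip(ext.col_labels, ext.counts[0]))
        assert col["OTU7"] == 3      # OTU1 + OTU2
        assert col["OTU6"] == 6      # OTU7 + OTU3
        assert col["OTU8"] == 9      # OTU4 + OTU5
        assert "OTU9" not in ext.col_labels  # root excluded
        assert ext.col_labels[: ext.q] == list(fig1_counts.columns)

    def test_matches_path_walking_oracle(self, fig1_tree):
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(
            rng.integers(0, 50, size=(6, 5)),
            columns=[f"OTU{i}" for i in range(1, 6)],
        )
        ext = build_extended_table(counts, fig1_tree)
        oracle = extended_counts_naive(counts, fig1_tree)
        for k in range(ext.q, ext.m):
            np.testing.assert_array_equal(
                ext.counts[:, k], oracle[int(ext.node_index[k])]
            )

    def test_zero_counts_propagate(self, fig1_tree):
        counts = pd.DataFrame(
            np.zeros((2, 5), dtype=int), columns=[f"OTU{i}" for i in range(1, 6)]
        )
        ext = build_extended_table(counts, fig1_tree)
        assert not ext.counts.any()

    def test_star_tree_equals_leaf_table(self):
        t = parse_newick("(A:1,B:1,C:1);")
        counts = pd.DataFrame([[3, 1, 2]], columns=["A", "B", "C"])
        ext = build_extended_table(counts, t)
        assert ext.m == ext.q == 3
        np.testing.assert_array_equal(ext.counts, counts.to_numpy())

    def test_column_order_follows_count_table(self, fig1_tree):
        counts = pd.DataFrame(
            [[5, 4, 3, 2, 1]], columns=["OTU5", "OTU4", "OTU3", "OTU2", "OTU1"]
        )
        ext = build_extended_table(counts, fig1_tree)
        assert ext.col_labels[:5] == ["OTU5", "OTU4", "OTU3", "OTU2", "OTU1"]
        col = dict(zip(ext.col_labels, ext.counts[0]))
        assert col["OTU7"] == col["OTU1"] + col["OTU2"] == 3

    @pytest.mark.parametrize(
        "bad",
        [
            pd.DataFrame([[1, 2]], columns=["OTU1", "OTUX"]),
            pd.DataFrame([[1, -2, 3, 4, 5]], columns=[f"OTU{i}" for i in range(1, 6)]),
            pd.DataFrame([[1.5, 2, 3, 4, 5]], columns=[f"OTU{i}" for i in range(1, 6)]),
        ],
    )
    def test_invalid_inputs_raise(self, fig1_tree, bad):
        with pytest.raises(ValueError):
            build_extended_table(bad, fig1_tree)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.lists(
            st.lists(st.integers(0, 1000), min_size=5, max_size=5),
            min_size=1,
            max_size=4,
        )
    )
    def test_internal_columns_sum_descendant_leaves(self, rows):
        tree = parse_newick(
            "(((OTU1:1,OTU2:1)OTU7:1,OTU3:1)OTU6:1,(OTU4:1,OTU5:1)OTU8:1)OTU9;"
        )
        counts = pd.DataFrame(rows, columns=[f"OTU{i}" for i in range(1, 6)])
        ext = build_extended_table(counts, tree)
        sets = tree.leaf_sets()
        for k in range(ext.q, ext.m):
            leaf_cols = ext.counts[:, :5][:, sets[int(ext.node_index[k])]]
            # leaf positions are tree-order; columns here are table order
            # (identical labels in this fixture), so direct summation applies
            np.testing.assert_array_equal(ext.counts[:, k], leaf_cols.sum(axis=1))


class TestRelativeAbundance:
    def test_star_normalization(self):
        t = parse_newick("(A:1,B:1,C:1);")
        counts = pd.DataFrame([[1, 1, 2]], columns=["A", "B", "C"])
        A = relative_abundance(build_extended_table(counts, t))
        np.testing.assert_allclose(A.values[0], [0.25, 0.25, 0.5])

    def test_fig1_internal_abundance(self, fig1_tree, fig1_counts):
        A = relative_abundance(build_extended_table(fig1_counts, fig1_tree))
        col = dict(zip(A.col_labels, A.values[0]))
        assert col["OTU6"] == pytest.approx(6 / 15)

    def test_single_nonzero_leaf_saturates_ancestors(self, fig1_tree):
        counts = pd.DataFrame(
            [[7, 0, 0, 0, 0]], columns=[f"OTU{i}" for i in range(1, 6)]
        )
        A = relative_abundance(build_extended_table(counts, fig1_tree))
        col = dict(zip(A.col_labels, A.values[0]))
        assert col["OTU1"] == col["OTU7"] == col["OTU6"] == 1.0
        assert col["OTU8"] == 0.0

    def test_zero_leaf_total_raises(self, fig1_tree):
        counts = pd.DataFrame(
            [[1, 1, 1, 1, 1], [0, 0, 0, 0, 0]],
            columns=[f"OTU{i}" for i in range(1, 6)],
            index=["ok", "empty"],
        )
        with pytest.raises(ValueError, match="empty"):
            relative_abundance(build_extended_table(counts, fig1_tree))

    def test_leaf_columns_sum_to_one(self, fig1_tree):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.integers(1, 30, size=(8, 5)), columns=[f"OTU{i}" for i in range(1, 6)]
        )
        A = relative_abundance(build_extended_table(counts, fig1_tree))
        np.testing.assert_allclose(A.values[:, :5].sum(axis=1), 1.0, atol=1e-12)


class TestRepresentations:
    @pytest.fixture
    def A(self, fig1_tree):
        rng = np.random.default_rng(11)
        counts = pd.DataFrame(
            rng.integers(0, 20, size=(10, 5)) * rng.integers(0, 2, size=(10, 5)) + 1,
            columns=[f"OTU{i}" for i in range(1, 6)],
        )
        return relative_abundance(build_extended_table(counts, fig1_tree))

    def test_indicator_and_sqrt(self, A):
        u = make_representation(A, "u")
        assert set(np.unique(u.M)) <= {0.0, 1.0}
        np.testing.assert_array_equal(u.M, (A.values > 0).astype(float))
        half = make_representation(A, ".5")
        w = make_representation(A, "w")
        np.testing.assert_allclose(half.M**2, w.M, atol=1e-12)

    def test_leaf_only_columns(self, A):
        a = make_representation(A, "a")
        assert a.M.shape[1] == A.q == 5
        np.testing.assert_array_equal(a.M, A.values[:, :5])
        assert a.col_labels == A.col_labels[:5]

    def test_unknown_kind_raises(self, A):
        with pytest.raises(ValueError, match="kind"):
            make_representation(A, "x")


class TestWeights:
    def test_hand_computed_binary_column(self):
        # two-sample column (0, 1): sample SD (n-1) = 1/sqrt(2); b_k = 2
        t = parse_newick("(A:2,B:1);")
        M = np.array([[0.0], [1.0]])
        w = compute_weights(M, t, "u", node_index=np.array([t.leaves[0]]))
        assert w[0] == pytest.approx(np.sqrt(0.5) * 2, abs=1e-5)
        assert w[0] == pytest.approx(1.41421, abs=1e-5)

    def test_constant_column_gets_zero_weight(self, fig1_tree):
        M = np.ones((6, 1))
        w = compute_weights(M, fig1_tree, "w", node_index=np.array([fig1_tree.leaves[0]]))
        assert w[0] == 0.0

    def test_leaf_only_ignores_branch_lengths(self, fig1_tree):
        rng = np.random.default_rng(5)
        M = rng.random((8, 5))
        w1 = compute_weights(M, fig1_tree, "a")
        scaled = parse_newick(
            "(((OTU1:9,OTU2:9)OTU7:9,OTU3:9)OTU6:9,(OTU4:9,OTU5:9)OTU8:9)OTU9;"
        )
        w2 = compute_weights(M, scaled, "a")
        np.testing.assert_array_equal(w1, w2)

    def test_branch_scaling_scales_weights(self, fig1_tree, fig1_counts):
        counts = pd.DataFrame(
            [[1, 2, 3, 4, 5], [5, 4, 3, 2, 1]],
            columns=[f"OTU{i}" for i in range(1, 6)],
        )
        A = relative_abundance(build_extended_table(counts, fig1_tree))
        rep = make_representation(A, "w")
        scaled_tree = parse_newick(
            "(((OTU1:3,OTU2:3)OTU7:3,OTU3:3)OTU6:3,(OTU4:3,OTU5:3)OTU8:3)OTU9;"
        )
        w_scaled = compute_weights(rep.M, scaled_tree, "w", node_index=rep.node_index)
        np.testing.assert_allclose(w_scaled, 3.0 * rep.omega, rtol=1e-12)

    def test_weights_invariant_to_sample_order(self, fig1_tree):
        rng = np.random.default_rng(9)
        counts = pd.DataFrame(
            rng.integers(1, 40, size=(12, 5)), columns=[f"OTU{i}" for i in range(1, 6)]
        )
        A1 = relative_abundance(build_extended_table(counts, fig1_tree))
        A2 = relative_abundance(
            build_extended_table(counts.iloc[::-1], fig1_tree)
        )
        for kind in ("u", "w", ".5", "a"):
            np.testing.assert_allclose(
                make_representation(A1, kind).omega,
                make_representation(A2, kind).omega,
                rtol=1e-12,
            )
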