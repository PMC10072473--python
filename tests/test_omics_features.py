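"""Gene selection, scaling, orderings, image tensors, mutation/CNV matrices."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from synscreen.containers import CNVMatrix, ExpressionMatrix
from synscreen.omics_features import (
    GeneList,
    GeneSetCollection,
    GeneImageLayout,
    MinMaxScalerState,
    binarize_mutations,
    filter_matrix_by_list,
    fit_apply_minmax,
    order_by_chromosome,
    order_by_clustering,
    pathway_mutation_matrix,
    reshape_to_image,
    select_genes,
    unreshape_image,
)


def _expr(values, genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{j}" for j in range(values.shape[1])]
    cells = cells or [f"C{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(cell_line_ids=cells, feature_names=genes, values=values)


class TestSelectGenes:
    def test_intersection(self):
        expr = _expr(np.arange(10.0).reshape(2, 5), genes=["G1", "G2", "G3", "G4", "G5"])
        out = select_genes(expr, GeneList("l", frozenset({"G2", "G4", "G9"})))
        assert out.gene_symbols == ["G2", "G4"]

    def test_union_of_lists_combined_semantics(self):
        expr = _expr(np.arange(10.0).reshape(2, 5), genes=["G1", "G2", "G3", "G4", "G5"])
        out = select_genes(
            expr,
            [GeneList("dgi", frozenset({"G1"})), GeneList("landmark", frozenset({"G3", "G5"}))],
        )
        assert out.gene_symbols == ["G1", "G3", "G5"]

    def test_constant_column_dropped(self):
        expr = _expr([[1.0, 5.0], [1.0, 6.0]], genes=["G1", "G2"])
        out = select_genes(expr, GeneList("l", frozenset({"G1", "G2"})), drop_constant=True)
        assert out.gene_symbols == ["G2"]

    def test_empty_intersection_errors(self):
        expr = _expr([[1.0]], genes=["G1"])
        with pytest.raises(ValueError, match="nope"):
            select_genes(expr, GeneList("nope", frozenset({"ZZZ"})))


class TestMinMaxScaling:
    def test_train_maps_to_unit_interval(self):
        train = np.array([[2.0], [4.0]])
        scaled, _, state = fit_apply_minmax(train)
        assert scaled.ravel().tolist() == [0.0, 1.0]

    def test_no_clipping_out_of_range(self):
        _, others, _ = fit_apply_minmax(np.array([[2.0], [4.0]]), [np.array([[5.0]])])
        assert others[0].item() == pytest.approx(1.5)

    def test_constant_column_rule(self):
        scaled, others, _ = fit_apply_minmax(
            np.array([[3.0], [3.0]]), [np.array([[7.0]])]
        )
        assert np.all(scaled == 0.0)
        assert np.all(others[0] == 0.0)

    def test_training_values_always_in_unit_interval(self, rng):
        train = rng.normal(size=(20, 7)) * 10
        scaled, _, _ = fit_apply_minmax(train)
        assert scaled.min() >= 0.0 and scaled.max() <= 1.0

    def test_serialization_round_trip_bit_exact(self, rng):
        train = rng.normal(size=(9, 4))
        test = rng.normal(size=(5, 4))
        state = MinMaxScalerState.fit(train)
        restored = MinMaxScalerState.from_json(state.to_json())
        np.testing.assert_array_equal(state.transform(test), restored.transform(test))


class TestOrderByChromosome:
    ANN = pd.DataFrame(
        {
            "symbol": ["g1", "g2", "g3", "gx", "gy"],
            "chromosome": ["1", "1", "2", "X", "22"],
            "start_bp": [100, 50, 10, 5, 1],
            "biotype": ["protein_coding"] * 5,
        }
    )

    def test_position_sort(self):
        layout = order_by_chromosome(["g1", "g2", "g3"], self.ANN)
        assert layout.permutation.tolist() == [1, 0, 2]  # g2, g1, g3

    def test_x_after_autosomes(self):
        layout = order_by_chromosome(["gx", "gy"], self.ANN)
        assert layout.permutation.tolist() == [1, 0]  # chr22 before chrX

    def test_unannotated_last_alphabetical(self):
        layout = order_by_chromosome(["zz", "aa", "g1"], self.ANN)
        assert layout.permutation.tolist() == [2, 1, 0]  # g1, aa, zz

    def test_tie_break_by_symbol(self):
        ann = pd.DataFrame(
            {
                "symbol": ["b", "a"],
                "chromosome": ["3", "3"],
                "start_bp": [7, 7],
                "biotype": ["pc", "pc"],
            }
        )
        assert order_by_chromosome(["b", "a"], ann).permutation.tolist() == [1, 0]


def _dendrogram_orders(Z, n):
    """All leaf orders consistent with the dendrogram (subtree flips)."""

    def expand(node):
        if node < n:
            return [[node]]
        left, right = int(Z[node - n, 0]), int(Z[node - n, 1])
        out = []
        for lo in expand(left):
            for ro in expand(right):
                out.append(lo + ro)
                out.append(ro + lo)
        return out

    return expand(2 * n - 2)


def _successive_cost(order, dist):
    return sum(dist[a, b] for a, b in itertools.pairwise(order))


class TestOrderByClustering:
    def test_two_genes_identity(self):
        expr = _expr([[0.0, 1.0], [1.0, 0.0], [2.0, 2.0]])
        assert order_by_clustering(expr).permutation.tolist() == [0, 1]

    def test_separates_uncorrelated_gene(self, rng):
        base = rng.normal(size=30)
        g1 = base + rng.normal(scale=0.1, size=30)
        g2 = base + rng.normal(scale=0.1, size=30)
        g3 = rng.normal(size=30)
        expr = _expr(np.column_stack([g1, g3, g2]))
        order = order_by_clustering(expr).permutation.tolist()
        assert abs(order.index(0) - order.index(2)) == 1  # correlated pair adjacent

    @pytest.mark.parametrize("n_genes,seed", [(5, 0), (6, 1), (7, 2), (7, 3)])
    def test_matches_brute_force_over_dendrogram_orders(self, n_genes, seed):
        """Optimal leaf ordering equals exhaustive minimum over consistent orders."""
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(12, n_genes))
        expr = _expr(X)
        layout = order_by_clustering(expr)
        condensed = pdist(X.T, metric="correlation")
        dist = squareform(condensed)
        Z = linkage(condensed, method="complete")
        best = min(
            _successive_cost(order, dist) for order in _dendrogram_orders(Z, n_genes)
        )
        got = _successive_cost(layout.permutation.tolist(), dist)
        assert got == pytest.approx(best, abs=1e-10)

    def test_constant_gene_rejected(self):
        expr = _expr([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0]])
        with pytest.raises(ValueError, match="constant gene"):
            order_by_clustering(expr)

    def test_emits_true_permutation(self, rng):
        expr = _expr(rng.normal(size=(10, 9)))
        perm = order_by_clustering(expr).permutation
        assert sorted(perm.tolist()) == list(range(9))


class TestReshapeToImage:
    def test_978_genes_to_32x32_with_46_pads(self, rng):
        row = rng.random(978)
        layout = GeneImageLayout(permutation=rng.permutation(978), shape=(978,))
        tensor, concrete = reshape_to_image(row, layout, "2d")
        assert tensor.shape == (32, 32)
        assert concrete.pad_count == 46

    def test_perfect_square_no_padding(self, rng):
        row = rng.random(9)
        layout = GeneImageLayout(permutation=np.arange(9), shape=(9,))
        tensor, concrete = reshape_to_image(row, layout, "2d")
        assert tensor.shape == (3, 3) and concrete.pad_count == 0

    def test_1d_shape(self, rng):
        row = rng.random(7)
        layout = GeneImageLayout(permutation=np.arange(7), shape=(7,))
        tensor, concrete = reshape_to_image(row, layout, "1d")
        assert tensor.shape == (7, 1) and concrete.pad_count == 0

    @pytest.mark.parametrize("mode", ["1d", "2d"])
    def test_round_trip_and_value_conservation(self, mode, rng):
        row = rng.random(11)
        layout = GeneImageLayout(permutation=rng.permutation(11), shape=(11,))
        tensor, concrete = reshape_to_image(row, layout, mode)
        non_pad = np.sort(tensor.reshape(-1))[concrete.pad_count:] if mode == "2d" else np.sort(tensor.ravel())
        # padding is zeros; the non-pad multiset equals the input multiset
        assert np.allclose(np.sort(tensor.reshape(-1))[-11:], np.sort(row)) or np.allclose(
            non_pad, np.sort(row)
        )
        np.testing.assert_allclose(unreshape_image(tensor, concrete), row)

    def test_length_mismatch(self, rng):
        layout = GeneImageLayout(permutation=np.arange(5), shape=(5,))
        with pytest.raises(ValueError, match="does not match"):
            reshape_to_image(rng.random(6), layout, "1d")

    def test_bad_permutation_rejected(self):
        with pytest.raises(ValueError, match="bijection"):
            GeneImageLayout(permutation=np.array([0, 0, 2]), shape=(3,))


class TestMutations:
    MAF = pd.DataFrame(
        {
            "Hugo_Symbol": ["G1", "G2", "G1", "G3", "G3", "G3"],
            "Variant_Classification": [
                "Missense_Mutation",
                "Silent",
                "Missense_Mutation",
                "Nonsense_Mutation",
                "Frame_Shift_Del",
                "Splice_Site",
            ],
            "Tumor_Sample_Barcode": ["C1", "C1", "C2", "C1", "C1", "C1"],
        }
    )

    def test_binarization_rules(self):
        matrix = binarize_mutations(self.MAF).to_frame()
        assert matrix.loc["C1", "G1"] == 1  # retained missense
        assert matrix.loc["C1", "G2"] == 0  # silent only
        assert matrix.loc["C1", "G3"] == 1  # three retained variants still 1
        assert matrix.loc["C2", "G1"] == 1

    def test_unknown_class_warns_and_retains(self):
        maf = pd.DataFrame(
            {
                "Hugo_Symbol": ["G1"],
                "Variant_Classification": ["Weird_Class"],
                "Tumor_Sample_Barcode": ["C1"],
            }
        )
        with pytest.warns(UserWarning, match="Weird_Class"):
            matrix = binarize_mutations(maf)
        assert matrix.to_frame().loc["C1", "G1"] == 1

    def test_pathway_or_semantics(self):
        gene_mut = binarize_mutations(self.MAF)
        sets = GeneSetCollection(
            {
                "P_hit": frozenset({"G1", "G2"}),   # G1 mutated -> 1
                "P_miss": frozenset({"G2"}),        # silent only -> 0
                "P_absent": frozenset({"G9"}),      # no matched genes -> dropped
            }
        )
        with pytest.warns(UserWarning, match="P_absent"):
            pw = pathway_mutation_matrix(gene_mut, sets)
        frame = pw.to_frame()
        assert frame.loc["C1", "P_hit"] == 1
        assert frame.loc["C1", "P_miss"] == 0
        assert "P_absent" not in frame.columns

    def test_pathway_zero_only_if_all_members_zero(self):
        gene_mut = binarize_mutations(self.MAF)
        sets = GeneSetCollection({"P": frozenset({"G1", "G2", "G3"})})
        pw = pathway_mutation_matrix(gene_mut, sets).to_frame()
        gm = gene_mut.to_frame()
        for cell in gm.index:
            assert pw.loc[cell, "P"] == int(gm.loc[cell, ["G1", "G2", "G3"]].any())


class TestFilterMatrixByList:
    CNV = CNVMatrix(
        cell_line_ids=["C1", "C2"],
        feature_names=["G1", "G2", "G3", "G4"],
        values=np.array([[0, 1, -2, 2], [1, 0, 0, -1]]),
    )

    def test_filter(self):
        out = filter_matrix_by_list(self.CNV, GeneList("l", frozenset({"G2", "G3"})))
        assert out.feature_names == ["G2", "G3"]
        assert isinstance(out, CNVMatrix)

    def test_disjoint_list_errors(self):
        with pytest.raises(ValueError, match="no genes"):
            filter_matrix_by_list(self.CNV, GeneList("l", frozenset({"ZZ"})))

    def test_idempotent(self):
        gl = GeneList("l", frozenset({"G1", "G4"}))
        once = filter_matrix_by_list(self.CNV, gl)
        twice = filter_matrix_by_list(once, gl)
        np.testing.assert_array_equal(once.values, twice.values)
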