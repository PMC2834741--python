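"""Neighbor joining, distances, and the tree container."""

import io

import numpy as np
import pytest

from alchevo.evo import PhyloTree, jc_distance_matrix, nj_tree


def additive_matrix():
    # distances generated by the unrooted tree ((A:1,B:2):3,C:4,D:5) with
    # the internal edge between {A,B} and {C,D}
    return np.array(
        [
            [0.0, 3.0, 8.0, 9.0],
            [3.0, 0.0, 9.0, 10.0],
            [8.0, 9.0, 0.0, 9.0],
            [9.0, 10.0, 9.0, 0.0],
        ]
    )


def branch_length_map(tree: PhyloTree) -> dict:
    return {
        tree.edge_bipartition(int(e)): float(tree.lengths[int(e)])
        for e in tree.edges
    }


class TestNeighborJoining:
    def test_three_taxa_solve_three_point_formulas(self):
        d = np.array([[0.0, 5.0, 9.0], [5.0, 0.0, 10.0], [9.0, 10.0, 0.0]])
        tree = nj_tree(d, ["A", "B", "C"])
        lengths = branch_length_map(tree)
        assert lengths[frozenset({"B"})] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths[frozenset({"C"})] == pytest.approx((9 + 10 - 5) / 2)
        # edge above A: canonical side excludes the anchor taxon A
        assert lengths[frozenset({"B", "C"})] == pytest.approx((5 + 9 - 10) / 2)

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        tree = nj_tree(additive_matrix(), ["A", "B", "C", "D"])
        lengths = branch_length_map(tree)
        assert lengths[frozenset({"B"})] == pytest.approx(2.0)
        assert lengths[frozenset({"C"})] == pytest.approx(4.0)
        assert lengths[frozenset({"D"})] == pytest.approx(5.0)
        assert lengths[frozenset({"C", "D"})] == pytest.approx(3.0)
        assert frozenset({"C", "D"}) in lengths  # the generating split

    def test_taxon_permutation_invariance(self):
        d = additive_matrix()
        order = [2, 0, 3, 1]
        tree1 = nj_tree(d, ["A", "B", "C", "D"])
        tree2 = nj_tree(d[np.ix_(order, order)],
                        [["A", "B", "C", "D"][i] for i in order])
        assert branch_length_map(tree1) == pytest.approx(branch_length_map(tree2))

    def test_negative_length_estimates_clamped_to_zero(self):
        d = np.array(
            [
                [0.0, 1.0, 1.0, 1.0],
                [1.0, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 0.1],
                [1.0, 1.0, 0.1, 0.0],
            ]
        )
        tree = nj_tree(d, ["A", "B", "C", "D"])
        assert (tree.lengths[list(tree.edges)] >= 0).all()

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(np.zeros((2, 2)), ["A", "B"])

    def test_asymmetric_matrix_rejected(self):
        d = additive_matrix()
        d[0, 1] = 99.0
        with pytest.raises(ValueError):
            nj_tree(d, ["A", "B", "C", "D"])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scikit_bio_topology(self, seed):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(seed)
        n = 7
        taxa = [f"t{i}" for i in range(n)]
        base = rng.uniform(0.5, 2.0, size=(n, n))
        d = (base + base.T) / 2.0
        np.fill_diagonal(d, 0.0)
        ours = nj_tree(d, taxa)
        dm = skbio.DistanceMatrix(d, ids=taxa)
        theirs = skbio.tree.nj(dm)
        ours_sk = skbio.TreeNode.read(io.StringIO(ours.to_newick()))
        rf = ours_sk.compare_rfd(theirs)
        assert rf == 0.0


class TestJCDistances:
    def test_identical_sequences_give_zero(self):
        d = jc_distance_matrix(["a", "b"], ["ACGTACGT", "ACGTACGT"])
        assert d[0, 1] == 0.0

    def test_known_proportion_matches_formula(self):
        # 2 differences over 8 sites: p = 0.25
        d = jc_distance_matrix(["a", "b"], ["ACGTACGT", "ACGTACAA"])
        expected = -0.75 * np.log(1 - 4 * 0.25 / 3)
        assert d[0, 1] == pytest.approx(expected, rel=1e-12)

    def test_gapped_positions_skipped(self):
        d = jc_distance_matrix(["a", "b"], ["AC-T", "ACGT"])
        assert d[0, 1] == 0.0

    def test_saturated_pair_capped_with_warning(self):
        with pytest.warns(UserWarning, match="saturated"):
            d = jc_distance_matrix(["a", "b"], ["AAAA", "CCCC"], max_distance=5.0)
        assert d[0, 1] == 5.0


class TestPhyloTree:
    def test_newick_round_trip(self):
        nwk = "(A:0.1,B:0.2,(C:0.15,D:0.3):0.05);"
        tree = PhyloTree.from_newick(nwk)
        again = PhyloTree.from_newick(tree.to_newick(), taxa=tree.taxa)
        assert branch_length_map(tree) == pytest.approx(branch_length_map(again))

    def test_rooted_newick_is_unrooted_on_parse(self):
        tree = PhyloTree.from_newick("((A:0.1,B:0.2):0.05,(C:0.15,D:0.3):0.05);")
        assert tree.is_fully_resolved_unrooted()
        assert tree.n_edges == 5

    def test_edge_count_matches_unrooted_formula(self, small_tree):
        assert small_tree.n_edges == 2 * small_tree.n_taxa - 3

    def test_postorder_visits_children_first(self, small_tree):
        order = small_tree.postorder()
        seen = set()
        for node in order:
            for child in small_tree.children(node):
                assert child in seen
            seen.add(node)
        assert order[-1] == small_tree.root

    def test_leafset_and_bipartition(self, small_tree):
        bips = {small_tree.edge_bipartition(int(e)) for e in small_tree.edges}
        assert frozenset({"C", "D"}) in bips

    def test_negative_lengths_rejected(self, small_tree):
        with pytest.raises(ValueError):
            small_tree.with_lengths(-np.ones(small_tree.n_nodes))
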