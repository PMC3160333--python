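"""Neighbor joining, bootstrap support, collapsing, paralog classification."""

import numpy as np
import pytest
from Bio.Phylo import BaseTree

from c1census import phylo
from c1census.phylo import (Msa, bipartitions, bootstrap_support,
                            classify_paralogs, collapse_low_support,
                            neighbor_joining, nj_tree, p_distance_matrix)
from oracles import tree_path_distances


class TestPDistance:
    def test_identical_rows_have_zero_distance(self):
        msa = Msa(("a", "b"), ("ACDE", "ACDE"))
        assert p_distance_matrix(msa)[0, 1] == 0.0

    def test_one_mismatch_in_four_columns(self):
        msa = Msa(("a", "b"), ("AAAA", "AAAT"))
        assert p_distance_matrix(msa)[0, 1] == 0.25

    def test_gap_columns_are_pairwise_deleted(self):
        msa = Msa(("a", "b"), ("A-CG", "ATCG"))
        assert p_distance_matrix(msa)[0, 1] == 0.0  # 3 compared, 0 mismatches

    def test_no_comparable_columns_is_error(self):
        msa = Msa(("a", "b"), ("A--", "-AA"))
        with pytest.raises(ValueError, match="gap-free"):
            p_distance_matrix(msa)

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="same length"):
            Msa(("a", "b"), ("AA", "AAA"))


class TestNeighborJoining:
    def test_three_equidistant_taxa_get_unit_pendants(self):
        d = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], dtype=float)
        tree = neighbor_joining(d, ["A", "B", "C"])
        lengths = {t.name: t.branch_length for t in tree.get_terminals()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 1.0}

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # distances from the tree ((A:1,B:2):1,(C:3,D:4))
        labels = ["A", "B", "C", "D"]
        d = np.array([[0, 3, 5, 6],
                      [3, 0, 6, 7],
                      [5, 6, 0, 7],
                      [6, 7, 7, 0]], dtype=float)
        tree = neighbor_joining(d, labels)
        assert bipartitions(tree, tuple(labels)) == {frozenset({"C", "D"})}
        np.testing.assert_allclose(tree_path_distances(tree, labels), d)
        pendants = {t.name: t.branch_length for t in tree.get_terminals()}
        assert pendants == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}

    @pytest.mark.parametrize("n_taxa,seed", [(4, 0), (5, 1), (6, 2), (7, 3), (8, 4)])
    def test_consistency_on_random_additive_matrices(self, n_taxa, seed):
        """NJ must return the generating topology and branch lengths for any
        additive matrix (here: path distances of random binary trees)."""
        rng = np.random.default_rng(seed)
        for _ in range(4):
            true_tree, labels = _random_binary_tree(rng, n_taxa)
            d = tree_path_distances(true_tree, labels)
            est = neighbor_joining(d, labels)
            assert bipartitions(est, tuple(labels)) == \
                bipartitions(true_tree, tuple(labels))
            np.testing.assert_allclose(tree_path_distances(est, labels), d,
                                       atol=1e-9)

    def test_matches_independent_nj_implementation(self):
        """Topology agreement with scikit-bio's neighbor joining."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(12)
        true_tree, labels = _random_binary_tree(rng, 6)
        d = tree_path_distances(true_tree, labels)
        mine = neighbor_joining(d, labels)
        ref = skbio.tree.nj(skbio.DistanceMatrix(d, labels))
        ref_splits = set()
        anchor = sorted(labels)[0]
        for node in ref.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= len(labels) - 2:
                if anchor in side:
                    side = frozenset(labels) - side
                ref_splits.add(side)
        assert bipartitions(mine, tuple(labels)) == ref_splits

    def test_distant_taxon_sits_on_its_own_root_branch(self):
        labels = ["A", "B", "C", "D"]
        d = np.array([[0, 1, 1, 10],
                      [1, 0, 1, 10],
                      [1, 1, 0, 10],
                      [10, 10, 10, 0]], dtype=float)
        tree = neighbor_joining(d, labels)
        root_leaves = {c.name for c in tree.root.clades if c.is_terminal()}
        assert "D" in root_leaves

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(d, ["A", "B", "C"])

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError, match="3 taxa"):
            neighbor_joining(np.zeros((2, 2)), ["A", "B"])


class TestBootstrap:
    strong_msa = Msa(("A", "B", "C", "D"),
                     ("A" * 24, "A" * 24, "T" * 24, "T" * 24))

    def test_unanimous_signal_gives_full_support(self):
        tree = bootstrap_support(self.strong_msa, n_replicates=50, seed=0)
        supports = [c.confidence for c in tree.get_nonterminals()
                    if c.confidence is not None]
        assert supports == [100.0]

    def test_single_replicate_supports_are_zero_or_hundred(self):
        msa = Msa(("A", "B", "C", "D", "E"),
                  ("ACGTACGTAC", "ACGTACGTAA", "TCGAACGAAC",
                   "TCGAACGTTT", "TCGATCGTTC"))
        tree = bootstrap_support(msa, n_replicates=1, seed=3)
        for c in tree.get_nonterminals():
            if c.confidence is not None:
                assert c.confidence in (0.0, 100.0)

    def test_fixed_seed_reproduces_supports(self):
        msa = Msa(("A", "B", "C", "D", "E"),
                  ("ACGTACGTAC", "ACGTACGTAA", "TCGAACGAAC",
                   "TCGAACGTTT", "TCGATCGTTC"))
        t1 = bootstrap_support(msa, n_replicates=30, seed=9)
        t2 = bootstrap_support(msa, n_replicates=30, seed=9)
        assert phylo.to_newick(t1) == phylo.to_newick(t2)

    def test_supports_invariant_under_leaf_permutation(self):
        msa = Msa(("A", "B", "C", "D", "E"),
                  ("ACGTACGTAC", "ACGTACGTAA", "TCGAACGAAC",
                   "TCGAACGTTT", "TCGATCGTTC"))
        perm = [3, 0, 4, 1, 2]
        permuted = Msa(tuple(msa.labels[i] for i in perm),
                       tuple(msa.rows[i] for i in perm))
        t1 = bootstrap_support(msa, n_replicates=40, seed=5)
        t2 = bootstrap_support(permuted, n_replicates=40, seed=5)
        s1 = _support_by_split(t1, msa.labels)
        s2 = _support_by_split(t2, msa.labels)
        assert s1 == s2


class TestCollapse:
    @staticmethod
    def _tree_with_support(support):
        a, b, c, d = (BaseTree.Clade(name=n, branch_length=1.0) for n in "ABCD")
        inner = BaseTree.Clade(branch_length=0.5, clades=[a, b],
                               confidence=support)
        root = BaseTree.Clade(clades=[inner, c, d])
        return BaseTree.Tree(root=root, rooted=False)

    def test_full_support_leaves_tree_unchanged(self):
        tree = self._tree_with_support(100.0)
        out = collapse_low_support(tree, 60.0)
        assert phylo.to_newick(out) == phylo.to_newick(tree)

    def test_zero_support_everywhere_gives_star(self):
        out = collapse_low_support(self._tree_with_support(0.0), 60.0)
        assert all(c.is_terminal() for c in out.root.clades)
        assert len(out.root.clades) == 4

    def test_threshold_is_strictly_less_than(self):
        kept = collapse_low_support(self._tree_with_support(60.0), 60.0)
        gone = collapse_low_support(self._tree_with_support(59.0), 60.0)
        assert len(kept.root.clades) == 3   # survives at exactly 60
        assert len(gone.root.clades) == 4   # contracted at 59

    def test_input_tree_is_not_mutated(self):
        tree = self._tree_with_support(10.0)
        before = phylo.to_newick(tree)
        collapse_low_support(tree, 60.0)
        assert phylo.to_newick(tree) == before


class TestClassifyParalogs:
    @staticmethod
    def _clade(name=None, children=(), length=1.0):
        return BaseTree.Clade(name=name, branch_length=length,
                              clades=list(children) or None)

    def test_query_sister_to_reference_leaf_joins_its_subgroup(self):
        c = self._clade
        tree = BaseTree.Tree(root=c(children=[
            c(children=[c("Q"), c("R1")]),
            c("R2"),
            c(children=[c("R3"), c("R4")]),
        ]), rooted=False)
        refs = {"R1": "X", "R2": "X", "R3": "Y", "R4": "Y"}
        assert classify_paralogs(tree, refs)["Q"] == "X"

    def test_query_between_subgroup_clades_is_unknown(self):
        c = self._clade
        tree = BaseTree.Tree(root=c(children=[
            c(children=[c("R1"), c("R2")]),
            c(children=[c("R3"), c("R4")]),
            c("Q"),
        ]), rooted=False)
        refs = {"R1": "X", "R2": "X", "R3": "Y", "R4": "Y"}
        assert classify_paralogs(tree, refs)["Q"] == "unknown"

    def test_single_subgroup_absorbs_every_query(self):
        c = self._clade
        tree = BaseTree.Tree(root=c(children=[
            c(children=[c("Q1"), c("R1")]), c("R2"), c("Q2")]), rooted=False)
        refs = {"R1": "X", "R2": "X"}
        out = classify_paralogs(tree, refs)
        assert out == {"Q1": "X", "Q2": "X"}

    def test_absent_query_leaf_is_error(self):
        c = self._clade
        tree = BaseTree.Tree(root=c(children=[c("R1"), c("R2"), c("Q")]),
                             rooted=False)
        with pytest.raises(KeyError, match="absent"):
            classify_paralogs(tree, {"R1": "X", "R2": "X"}, queries=["nope"])


class TestNewick:
    def test_round_trip_is_byte_identical(self):
        msa = Msa(("A", "B", "C", "D"),
                  ("ACGTACGTAC", "ACGTACGTAA", "TCGAACGAAC", "TCGAACGTTT"))
        tree = bootstrap_support(msa, n_replicates=10, seed=1)
        first = phylo.to_newick(tree)
        second = phylo.to_newick(phylo.read_newick(first))
        assert first == second


def _random_binary_tree(rng, n_taxa):
    labels = [f"T{i}" for i in range(n_taxa)]
    nodes = [BaseTree.Clade(name=lab, branch_length=float(rng.uniform(0.5, 2.0)))
             for lab in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = BaseTree.Clade(branch_length=float(rng.uniform(0.5, 2.0)),
                                clades=[nodes[i], nodes[j]])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    root = BaseTree.Clade(clades=nodes)
    return BaseTree.Tree(root=root, rooted=False), labels


def _support_by_split(tree, taxa):
    all_taxa = frozenset(taxa)
    anchor = sorted(all_taxa)[0]
    out = {}
    for clade in tree.get_nonterminals():
        if clade is tree.root or clade.confidence is None:
            continue
        side = frozenset(t.name for t in clade.get_terminals())
        if anchor in side:
            side = all_taxa - side
        out[side] = clade.confidence
    return out
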