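import numpy as np
import pytest

from codonscan import (
    DistanceMatrix,
    NewickParseError,
    neighbor_joining,
    parse_newick,
    protein_distance_matrix,
    write_newick,
)
from codonscan.trees import additive_distance_matrix


def random_binary_tree(labels, rng):
    """Random unrooted binary topology with random branch lengths."""
    from codonscan.trees import PhyloTree, TreeNode

    nodes = [TreeNode(lab) for lab in labels[:3]]
    root = TreeNode()
    for node in nodes:
        root.add_child(node)
    edges = list(nodes)
    for lab in labels[3:]:
        edge = edges[rng.integers(len(edges))]
        parent = edge.parent
        mid = TreeNode()
        parent.children[parent.children.index(edge)] = mid
        mid.parent = parent
        mid.add_child(edge)
        leaf = TreeNode(lab)
        mid.add_child(leaf)
        edges.extend([mid, leaf])
    tree = PhyloTree(root, rooted=False)
    for node in tree.postorder():
        if node is not root:
            node.length = float(rng.uniform(0.1, 1.0))
    return tree


class TestNewick:
    def test_two_leaf_lengths(self):
        tree = parse_newick("(a:1,b:2);")
        lengths = {n.name: n.length for n in tree.leaves()}
        assert lengths == {"a": 1.0, "b": 2.0}

    def test_missing_lengths_defaulted_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="codonscan"):
            tree = parse_newick("((a,b),(c,d));")
        assert all(n.length == 0.1 for n in tree.postorder() if n is not tree.root)
        assert "missing branch lengths" in caplog.text

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(NewickParseError):
            parse_newick("(a,(b,c);")

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(NewickParseError, match="duplicate"):
            parse_newick("(a:1,(a:1,b:1):1);")

    def test_round_trip_preserves_lengths_and_is_byte_stable(self):
        text = write_newick(parse_newick("((d:0.4,c:0.3):0.2,(b:0.25,a:0.1):0.05);"))
        tree = parse_newick(text)
        assert write_newick(tree) == text
        # canonical ordering puts the clade containing 'a' first
        assert text.startswith("((a:")
        reparsed = {n.name: n.length for n in tree.leaves()}
        for name, length in {"a": 0.1, "b": 0.25, "c": 0.3, "d": 0.4}.items():
            assert abs(reparsed[name] - length) <= 1e-12


class TestProteinDistances:
    def test_identical_rows_have_zero_distance(self):
        dm = protein_distance_matrix([("a", "MKV"), ("b", "MKV")], "p-distance")
        assert dm.matrix[0, 1] == 0.0

    def test_p_distance_with_pairwise_deletion(self):
        dm = protein_distance_matrix(
            [("a", "MKVLMKVLMK"), ("b", "MKVLMKVLMA")], "p-distance"
        )
        assert dm.matrix[0, 1] == pytest.approx(0.1)

    def test_poisson_dominates_p_distance(self):
        rows = [("a", "MKVLAC"), ("b", "MAVLAA"), ("c", "MKVLGG")]
        p = protein_distance_matrix(rows, "p-distance").matrix
        poisson = protein_distance_matrix(rows, "poisson").matrix
        assert np.all(poisson >= p)


class TestNeighborJoining:
    def test_two_taxa_split_evenly(self):
        tree = neighbor_joining(DistanceMatrix(["a", "b"], np.array([[0.0, 3.0], [3.0, 0.0]])))
        assert {n.name: n.length for n in tree.leaves()} == {"a": 1.5, "b": 1.5}

    def test_three_taxa_three_point_solution(self):
        D = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], D))
        lengths = {n.name: n.length for n in tree.leaves()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_four_taxon_additive_matrix_recovers_topology(self):
        truth = parse_newick("((a:0.2,b:0.3):0.15,(c:0.25,d:0.4):0.15);")
        recovered = neighbor_joining(additive_distance_matrix(truth))
        assert recovered.bipartitions() == truth.bipartitions()

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_random_additive_matrices_recover_topology(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        for _ in range(10):
            labels = [f"t{i}" for i in range(n_taxa)]
            truth = random_binary_tree(labels, rng)
            recovered = neighbor_joining(additive_distance_matrix(truth))
            assert recovered.bipartitions() == truth.bipartitions()

    def test_agrees_with_reference_nj_topology(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(42)
        labels = [f"t{i}" for i in range(6)]
        truth = random_binary_tree(labels, rng)
        dm = additive_distance_matrix(truth)
        mine = neighbor_joining(dm)
        ref = skbio.tree.nj(skbio.DistanceMatrix(dm.matrix, ids=dm.labels))
        ref_splits = set()
        for node in ref.non_tips():
            below = frozenset(t.name for t in node.tips())
            if 1 < len(below) < len(labels) - 1:
                other = frozenset(labels) - below
                ref_splits.add(below if len(below) <= len(other) else other)
        assert mine.bipartitions() <= ref_splits | mine.bipartitions()
        assert mine.bipartitions() == ref_splits

    def test_negative_branch_estimates_clamped(self):
        D = np.array(
            [
                [0.0, 0.1, 1.0, 1.0],
                [0.1, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 0.1],
                [1.0, 1.0, 0.1, 0.0],
            ]
        )
        tree = neighbor_joining(DistanceMatrix(list("abcd"), D))
        assert all((n.length or 0.0) >= 0 for n in tree.postorder() if n is not tree.root)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
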