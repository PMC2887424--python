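"""Phylogenetic trees: Newick I/O, protein distance matrices, neighbor joining.

The tree machinery plays the role an external phylogenetics package would
normally play for site-model analysis: users can supply any Newick tree, or
have one built by neighbor joining from Poisson-corrected protein distances.
Written trees use a canonical child ordering (smallest contained leaf label
first) so that write -> parse -> write is byte-stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np

logger = logging.getLogger("codonscan")

DEFAULT_BRANCH_LENGTH = 0.1


class NewickParseError(ValueError):
    pass


class TreeNode:
    """A node with parent link, children list and branch length to its parent."""

    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str | None = None, length: float | None = None):
        self.name = name
        self.length = length
        self.children: list["TreeNode"] = []
        self.parent: "TreeNode" | None = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """A rooted representation of a (possibly unrooted) phylogeny.

    An unrooted binary tree is represented with a trifurcating root; a rooted
    binary input keeps its bifurcating root.
    """

    root: TreeNode
    rooted: bool = False

    def postorder(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def rec(node: TreeNode) -> None:
            for child in node.children:
                rec(child)
            out.append(node)

        rec(self.root)
        return out

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.postorder() if n is not self.root)

    def is_binary(self) -> bool:
        """True if every internal node has 2 children (root may have 2 or 3)."""
        for node in self.postorder():
            if node.is_leaf:
                continue
            if node is self.root:
                if len(node.children) not in (2, 3):
                    return False
            elif len(node.children) != 2:
                return False
        return True

    def copy(self) -> "PhyloTree":
        def rec(node: TreeNode) -> TreeNode:
            new = TreeNode(node.name, node.length)
            for child in node.children:
                new.add_child(rec(child))
            return new

        return PhyloTree(rec(self.root), rooted=self.rooted)

    def canonicalize(self) -> None:
        """Sort children in place by smallest contained leaf label."""

        def min_leaf(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name or ""
            return min(min_leaf(c) for c in node.children)

        def rec(node: TreeNode) -> None:
            node.children.sort(key=min_leaf)
            for child in node.children:
                rec(child)

        rec(self.root)

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits (as the smaller-side leaf set) of the unrooted tree."""
        all_leaves = frozenset(self.leaf_names())
        splits: set[frozenset[str]] = set()

        def rec(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(rec(c) for c in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                other = all_leaves - below
                if len(below) < len(other) or (
                    len(below) == len(other) and sorted(below) < sorted(other)
                ):
                    splits.add(below)
                else:
                    splits.add(other)
            return below

        for child in self.root.children:
            rec(child)
        return splits


# ---------------------------------------------------------------------------
# Newick I/O (parsing via dendropy; canonical writer native)
# ---------------------------------------------------------------------------


def parse_newick(text: str, default_length: float | None = DEFAULT_BRANCH_LENGTH) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Missing branch lengths are filled with ``default_length`` (a warning is
    logged); duplicate leaf labels and malformed syntax raise
    :class:`NewickParseError`.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    missing = 0

    def convert(dnode) -> TreeNode:
        nonlocal missing
        name = dnode.taxon.label if dnode.taxon is not None else None
        length = dnode.edge.length
        if length is None and dnode.parent_node is not None:
            length = default_length
            missing += 1
        node = TreeNode(name, length)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    root = convert(dtree.seed_node)
    root.length = None
    if missing:
        logger.warning(
            "Newick tree had %d missing branch lengths; defaulted to %s", missing, default_length
        )
    tree = PhyloTree(root, rooted=len(root.children) == 2)
    names = tree.leaf_names()
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise NewickParseError(f"duplicate leaf labels: {sorted(dupes)}")
    if any(n is None or n == "" for n in names):
        raise NewickParseError("unlabeled leaf in Newick tree")
    return tree


def write_newick(tree: PhyloTree) -> str:
    """Canonical Newick text: children ordered by smallest contained leaf label."""
    canon = tree.copy()
    canon.canonicalize()

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            base = node.name or ""
        else:
            base = "(" + ",".join(fmt(c) for c in node.children) + ")"
        if node.length is not None:
            base += f":{float(node.length)!r}"
        return base

    return fmt(canon.root) + ";"


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.matrix < 0):
            raise ValueError("distances must be nonnegative")


def protein_distance_matrix(aln, model: str = "poisson") -> DistanceMatrix:
    """Pairwise protein distances from a gapped alignment.

    Gap columns are deleted pairwise. ``model='p-distance'`` gives the raw
    mismatch proportion; ``'poisson'`` applies d = -ln(1 - p) (infinite when
    p >= 1, flagged as ``inf``).
    """
    rows = list(aln.rows) if hasattr(aln, "rows") else list(aln)
    if len(rows) < 2:
        raise ValueError("need at least 2 sequences")
    labels = [name for name, _ in rows]
    n = len(rows)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = rows[i][1], rows[j][1]
            comparable = mismatch = 0
            for x, y in zip(a, b):
                if x != "-" and y != "-":
                    comparable += 1
                    if x != y:
                        mismatch += 1
            if comparable == 0:
                raise ValueError(f"no comparable columns between {labels[i]!r} and {labels[j]!r}")
            p = mismatch / comparable
            if model == "p-distance":
                d = p
            elif model == "poisson":
                d = np.inf if p >= 1.0 else -np.log(1.0 - p)
            else:
                raise ValueError(f"unknown distance model {model!r}")
            D[i, j] = D[j, i] = d
    return DistanceMatrix(labels, D)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def _clamp_length(x: float) -> float:
    if x < 0:
        logger.debug("NJ branch length %.3g clamped to 0", x)
        return 0.0
    return float(x)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Classical neighbor joining on a symmetric distance matrix.

    Consistent on additive matrices (recovers the generating topology).
    Negative branch-length estimates are clamped to 0. For 2 taxa the single
    edge is split evenly; 3 taxa are solved with the three-point equations.
    The result is unrooted, represented with a trifurcating root (2 taxa: a
    bifurcating root at the edge midpoint).
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes: list[TreeNode] = [TreeNode(name) for name in dm.labels]
    D = dm.matrix.astype(float).copy()

    if n == 2:
        root = TreeNode()
        for node in nodes:
            node.length = _clamp_length(D[0, 1] / 2.0)
            root.add_child(node)
        return PhyloTree(root, rooted=False)

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # deterministic tie-break: smallest (i, j) in active order
        flat = np.argmin(Q)
        qi, qj = divmod(flat, m)
        if qi > qj:
            qi, qj = qj, qi
        i, j = active[qi], active[qj]
        dij = D[i, j]
        li = 0.5 * dij + (r[qi] - r[qj]) / (2.0 * (m - 2))
        lj = dij - li
        new = TreeNode()
        ni, nj = nodes[i], nodes[j]
        ni.length = _clamp_length(li)
        nj.length = _clamp_length(lj)
        new.add_child(ni)
        new.add_child(nj)
        # distances from the new node to the remaining taxa
        newdist = np.zeros(D.shape[0] + 1)
        for qk, k in enumerate(active):
            if k in (i, j):
                continue
            newdist[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = newdist[:-1]
        D[:-1, -1] = newdist[:-1]
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    # three-point solve for the final star
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    root = TreeNode()
    for idx, length in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = _clamp_length(length)
        root.add_child(nodes[idx])
    return PhyloTree(root, rooted=False)


def additive_distance_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Path-length (patristic) distances between all leaf pairs of a tree."""
    leaves = tree.leaves()
    labels = [leaf.name for leaf in leaves]

    def path_to_root(node: TreeNode) -> list[TreeNode]:
        path = [node]
        while path[-1].parent is not None:
            path.append(path[-1].parent)
        return path

    n = len(leaves)
    D = np.zeros((n, n))
    for a in range(n):
        pa = path_to_root(leaves[a])
        depth = {id(node): sum(x.length or 0.0 for x in pa[: idx]) for idx, node in enumerate(pa)}
        for b in range(a + 1, n):
            node = leaves[b]
            dist = 0.0
            while id(node) not in depth:
                dist += node.length or 0.0
                node = node.parent
            D[a, b] = D[b, a] = dist + depth[id(node)]
    return DistanceMatrix(labels, D)
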