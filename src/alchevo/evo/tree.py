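"""Unrooted phylogenies, neighbor joining, and nucleotide distances.

`PhyloTree` is a light array-backed tree: leaves are nodes ``0..N-1`` (in
taxon order), internal nodes follow, and the structure is stored rooted at an
internal node purely for traversal — for a fully resolved unrooted tree of N
taxa the storage root has three children and there are 2N-3 edges.  Branch
lengths are expected substitutions per site/codon on the edge above each
node.  Newick parsing goes through dendropy.

`nj_tree` is the Saitou-Nei neighbor-joining algorithm with a deterministic
tie-break (lowest index pair on equal Q) and negative branch-length clamping.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np

__all__ = ["PhyloTree", "nj_tree", "jc_distance_matrix"]


@dataclass(frozen=True)
class PhyloTree:
    """Array-backed unrooted phylogeny.

    Attributes
    ----------
    taxa : tuple of str
        Leaf names; leaf ``i`` is node ``i``.
    parent : ndarray of int
        Parent node id per node; -1 for the storage root.
    lengths : ndarray of float
        Length of the edge above each node (0 for the storage root).
    root : int
        Storage-root node id.
    """

    taxa: tuple[str, ...]
    parent: np.ndarray
    lengths: np.ndarray
    root: int

    def __init__(self, taxa, parent, lengths, root):
        taxa = tuple(str(t) for t in taxa)
        parent = np.asarray(parent, dtype=int)
        lengths = np.asarray(lengths, dtype=float)
        if parent.shape != lengths.shape:
            raise ValueError("parent and lengths must have equal length")
        if (lengths[np.arange(parent.size) != root] < 0).any():
            raise ValueError("branch lengths must be non-negative")
        object.__setattr__(self, "taxa", taxa)
        object.__setattr__(self, "parent", parent)
        object.__setattr__(self, "lengths", lengths)
        object.__setattr__(self, "root", int(root))

    # -- basic structure -------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def edges(self) -> np.ndarray:
        """Edge ids: every node except the storage root (edge above node)."""
        return np.array([i for i in range(self.n_nodes) if i != self.root])

    @property
    def n_edges(self) -> int:
        return self.n_nodes - 1

    def children(self, node: int) -> list[int]:
        return [i for i in range(self.n_nodes) if self.parent[i] == node]

    def postorder(self) -> list[int]:
        """Nodes in postorder (children before parents), root last."""
        kids: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                kids[p].append(i)
        out: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(kids[node])
        return out[::-1]

    def is_fully_resolved_unrooted(self) -> bool:
        """True when every internal node has unrooted degree 3."""
        if self.n_taxa < 3:
            return False
        degree = np.zeros(self.n_nodes, dtype=int)
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                degree[i] += 1
                degree[p] += 1
        internal = np.ones(self.n_nodes, dtype=bool)
        internal[: self.n_taxa] = False
        return bool((degree[internal] == 3).all()) and self.n_edges == 2 * self.n_taxa - 3

    def leafset_below(self, node: int) -> frozenset[str]:
        """Leaf names in the subtree below `node` (given the storage rooting)."""
        kids: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                kids[p].append(i)
        out: set[str] = set()
        stack = [node]
        while stack:
            n = stack.pop()
            if n < self.n_taxa:
                out.add(self.taxa[n])
            stack.extend(kids[n])
        return frozenset(out)

    def edge_bipartition(self, edge: int) -> frozenset[str]:
        """Canonical side of the bipartition induced by `edge`: the side not
        containing the lexicographically smallest taxon."""
        below = self.leafset_below(edge)
        anchor = min(self.taxa)
        return frozenset(set(self.taxa) - below) if anchor in below else below

    def with_lengths(self, lengths: Sequence[float]) -> "PhyloTree":
        return PhyloTree(self.taxa, self.parent, lengths, self.root)

    # -- newick ----------------------------------------------------------
    def to_newick(self) -> str:
        kids: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                kids[p].append(i)

        def render(node: int) -> str:
            if node < self.n_taxa:
                label = self.taxa[node]
            else:
                label = ""
            if kids[node]:
                inner = ",".join(
                    f"{render(c)}:{self.lengths[c]:.10g}" for c in kids[node]
                )
                return f"({inner}){label}"
            return label

        return render(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str, taxa: Sequence[str] | None = None) -> "PhyloTree":
        """Parse a newick string (rooted inputs are unrooted by collapsing a
        bifurcating basal node).  `taxa` fixes the leaf order if given."""
        dt = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        seed = dt.seed_node
        if len(seed.child_nodes()) == 2 and sum(1 for _ in dt.leaf_node_iter()) >= 3:
            dt.collapse_basal_bifurcation()
        leaf_names = [lf.taxon.label for lf in dt.leaf_node_iter()]
        if taxa is None:
            taxa = leaf_names
        if sorted(taxa) != sorted(leaf_names):
            raise ValueError("taxa do not match newick leaf labels")
        name_to_id = {t: i for i, t in enumerate(taxa)}
        n_leaves = len(taxa)
        ids: dict[int, int] = {}
        next_internal = n_leaves
        nodes = list(dt.preorder_node_iter())
        for nd in nodes:
            if nd.is_leaf():
                ids[id(nd)] = name_to_id[nd.taxon.label]
            else:
                ids[id(nd)] = next_internal
                next_internal += 1
        parent = np.full(next_internal, -1, dtype=int)
        lengths = np.zeros(next_internal)
        for nd in nodes:
            if nd.parent_node is not None:
                parent[ids[id(nd)]] = ids[id(nd.parent_node)]
                lengths[ids[id(nd)]] = max(float(nd.edge.length or 0.0), 0.0)
        return cls(taxa, parent, lengths, ids[id(seed)])


def jc_distance_matrix(
    taxa: Sequence[str], seqs: Sequence[str], max_distance: float = 5.0
) -> np.ndarray:
    """Jukes-Cantor-corrected nucleotide distances from aligned sequences.

    Pairwise positions where either sequence has a gap or a non-ACGT symbol
    are skipped.  Saturated pairs (p >= 3/4) are set to `max_distance` with a
    warning.
    """
    n = len(taxa)
    if len(seqs) != n:
        raise ValueError("taxa and seqs lengths differ")
    arrs = [np.frombuffer(s.upper().encode(), dtype="S1") for s in seqs]
    if len({a.size for a in arrs}) != 1:
        raise ValueError("sequences must be aligned to equal length")
    valid = [np.isin(a, np.array([b"A", b"C", b"G", b"T"])) for a in arrs]
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        both = valid[i] & valid[j]
        m = both.sum()
        if m == 0:
            raise ValueError(f"no comparable sites between {taxa[i]} and {taxa[j]}")
        p = float((arrs[i][both] != arrs[j][both]).sum()) / m
        arg = 1.0 - 4.0 * p / 3.0
        if arg <= 0:
            warnings.warn(
                f"saturated distance between {taxa[i]} and {taxa[j]}; "
                f"capped at {max_distance}",
                stacklevel=2,
            )
            dist = max_distance
        else:
            dist = min(-0.75 * math.log(arg), max_distance)
        d[i, j] = d[j, i] = dist
    return d


def nj_tree(distances: np.ndarray, taxa: Sequence[str]) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Deterministic: on equal Q criterion the lowest-index pair is joined;
    negative branch-length estimates are clamped to 0.  Requires a symmetric
    non-negative matrix with zero diagonal and at least 3 taxa.
    """
    d = np.asarray(distances, dtype=float)
    n = len(taxa)
    if d.shape != (n, n):
        raise ValueError("distance matrix shape does not match taxa")
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if (d < 0).any() or not np.allclose(np.diag(d), 0.0):
        raise ValueError("distances must be non-negative with zero diagonal")

    # active nodes: global node ids; leaves 0..n-1, internals appended
    parent: list[int] = [-1] * n
    lengths: list[float] = [0.0] * n
    active: list[int] = list(range(n))
    dist = {
        (i, j): d[i, j] for i in range(n) for j in range(n) if i != j
    }

    def get(a: int, b: int) -> float:
        return dist[(a, b)]

    while len(active) > 3:
        m = len(active)
        r = {a: sum(get(a, b) for b in active if b != a) for a in active}
        best = None
        best_q = math.inf
        for ai in range(m):
            for bi in range(ai + 1, m):
                a, b = active[ai], active[bi]
                q = (m - 2) * get(a, b) - r[a] - r[b]
                if q < best_q - 1e-12:
                    best_q, best = q, (a, b)
        a, b = best
        u = len(parent)
        parent.append(-1)
        lengths.append(0.0)
        la = 0.5 * get(a, b) + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = get(a, b) - la
        parent[a] = u
        parent[b] = u
        lengths[a] = max(la, 0.0)
        lengths[b] = max(lb, 0.0)
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (get(a, c) + get(b, c) - get(a, b))
            dist[(u, c)] = dist[(c, u)] = max(duc, 0.0)
        active = [x for x in active if x not in (a, b)] + [u]

    # join the last three nodes at the storage root (three-point formulas)
    a, b, c = active
    root = len(parent)
    parent.append(-1)
    lengths.append(0.0)
    la = 0.5 * (get(a, b) + get(a, c) - get(b, c))
    lb = 0.5 * (get(a, b) + get(b, c) - get(a, c))
    lc = 0.5 * (get(a, c) + get(b, c) - get(a, b))
    for node, ln in ((a, la), (b, lb), (c, lc)):
        parent[node] = root
        lengths[node] = max(ln, 0.0)
    return PhyloTree(taxa, parent, lengths, root)
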