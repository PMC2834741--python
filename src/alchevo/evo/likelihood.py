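"""Felsenstein pruning for codon models on unrooted trees.

Site patterns are compressed before the recursion (identical columns share
one computation; the result is exactly invariant to compression).  Partial
likelihoods are rescaled per node to avoid underflow.  `PruningEngine`
precomputes everything that depends only on the data and topology (patterns,
leaf partials, traversal order) so repeated evaluations during optimization
only pay for the transition matrices and the upward pass.
"""

from __future__ import annotations

import numpy as np

from .codons import GAP_CODE, SENSE_CODONS, CodonAlignment
from .gy94 import CodonSubstModel, TransitionMatrixFactory
from .tree import PhyloTree

__all__ = ["pruning_loglik", "compress_patterns", "site_logliks", "PruningEngine"]

_N = len(SENSE_CODONS)
_SCALE_FLOOR = 1e-280


def compress_patterns(alignment: CodonAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Unique site columns and their multiplicities.

    Returns (patterns, counts) with patterns of shape (n_patterns, n_taxa).
    """
    cols = alignment.codons.T
    patterns, counts = np.unique(cols, axis=0, return_counts=True)
    return patterns, counts


class PruningEngine:
    """Reusable pruning recursion for one (alignment, topology) pair.

    Branch lengths, branch classes and model parameters vary call to call;
    the compressed patterns, leaf partial likelihoods and traversal order are
    fixed at construction.
    """

    def __init__(self, alignment: CodonAlignment, tree: PhyloTree) -> None:
        if tuple(sorted(alignment.taxa)) != tuple(sorted(tree.taxa)):
            raise ValueError("alignment and tree taxa differ")
        aligned = alignment.reordered(tree.taxa)
        self.tree = tree
        self.patterns, self.counts = compress_patterns(aligned)
        self.n_patterns = self.patterns.shape[0]
        self.n_sites = int(self.counts.sum())

        kids: list[list[int]] = [[] for _ in range(tree.n_nodes)]
        for i in range(tree.n_nodes):
            p = tree.parent[i]
            if p >= 0:
                kids[p].append(i)
        self._kids = kids
        self._internal_postorder = [
            n for n in tree.postorder() if n >= tree.n_taxa
        ]
        self._leaf_partials: list[np.ndarray] = []
        for leaf in range(tree.n_taxa):
            codes = self.patterns[:, leaf]
            part = np.zeros((_N, self.n_patterns))
            known = codes != GAP_CODE
            part[codes[known], np.nonzero(known)[0]] = 1.0
            part[:, ~known] = 1.0
            self._leaf_partials.append(part)

    def data_signature(self) -> tuple:
        """Hashable identity of the underlying data (taxa set + columns)."""
        return (
            tuple(sorted(self.tree.taxa)),
            self.patterns.tobytes(),
            self.counts.tobytes(),
        )

    def site_logliks(
        self,
        pi: np.ndarray,
        factory: TransitionMatrixFactory,
        branch_classes: np.ndarray,
        lengths: np.ndarray,
    ) -> np.ndarray:
        """Per-pattern log-likelihoods for the given parameters."""
        tree = self.tree
        pmats = {}
        for node in range(tree.n_nodes):
            if node == tree.root:
                continue
            pmats[node] = factory.probabilities(
                int(branch_classes[node]), float(lengths[node])
            )
        partial: dict[int, np.ndarray] = {
            leaf: self._leaf_partials[leaf] for leaf in range(tree.n_taxa)
        }
        log_scale = np.zeros(self.n_patterns)
        for node in self._internal_postorder:
            prod = np.ones((_N, self.n_patterns))
            for child in self._kids[node]:
                prod *= pmats[child] @ partial[child]
                del partial[child]
            scale = prod.max(axis=0)
            scale = np.where(scale > _SCALE_FLOOR, scale, 1.0)
            log_scale += np.log(scale)
            partial[node] = prod / scale
        site_like = pi @ partial[tree.root]
        if (site_like <= 0).any():
            raise FloatingPointError("zero site likelihood (underflow or bad model)")
        return np.log(site_like) + log_scale

    def loglik(self, pi, factory, branch_classes, lengths) -> float:
        return float(
            self.site_logliks(pi, factory, branch_classes, lengths) @ self.counts
        )


def _resolve_classes(tree: PhyloTree, model: CodonSubstModel,
                     branch_classes: np.ndarray | None) -> np.ndarray:
    if branch_classes is None:
        branch_classes = np.zeros(tree.n_nodes, dtype=int)
    else:
        branch_classes = np.asarray(branch_classes, dtype=int)
        if branch_classes.shape != (tree.n_nodes,):
            raise ValueError("branch_classes must give one class per node")
    used = {int(c) for i, c in enumerate(branch_classes) if i != tree.root}
    missing = used - set(model.omega_by_class)
    if missing:
        raise KeyError(f"branch classes with no omega assigned: {sorted(missing)}")
    return branch_classes


def site_logliks(
    alignment: CodonAlignment,
    tree: PhyloTree,
    model: CodonSubstModel,
    branch_classes: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pattern log-likelihoods and pattern counts.

    `branch_classes[node]` is the omega class of the edge above `node`
    (ignored for the storage root); default is class 0 everywhere.  Gap codes
    are treated as fully ambiguous states.
    """
    engine = PruningEngine(alignment, tree)
    branch_classes = _resolve_classes(tree, model, branch_classes)
    factory = TransitionMatrixFactory(model)
    logs = engine.site_logliks(
        model.codon_frequencies, factory, branch_classes, tree.lengths
    )
    return logs, engine.counts


def pruning_loglik(
    alignment: CodonAlignment,
    tree: PhyloTree,
    model: CodonSubstModel,
    branch_classes: np.ndarray | None = None,
) -> float:
    """Total log-likelihood of the alignment under the branch codon model."""
    logs, counts = site_logliks(alignment, tree, model, branch_classes)
    return float(logs @ counts)
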