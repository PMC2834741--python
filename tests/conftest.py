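"""Shared fixtures and independent oracles.

The oracle functions here are deliberately naive re-derivations (exhaustive
enumeration, fine-grid root bracketing) kept independent of the package's
own code paths so they can serve as cross-checks.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from alchevo.constants import kt
from alchevo.evo.codons import SENSE_CODONS, CodonAlignment
from alchevo.evo.gy94 import CodonSubstModel, TransitionMatrixFactory
from alchevo.evo.tree import PhyloTree


def brute_force_loglik(
    alignment: CodonAlignment,
    tree: PhyloTree,
    model: CodonSubstModel,
    branch_classes: np.ndarray | None = None,
) -> float:
    """Log-likelihood by exhaustive summation over internal-node states."""
    if branch_classes is None:
        branch_classes = np.zeros(tree.n_nodes, dtype=int)
    factory = TransitionMatrixFactory(model)
    pmats = {
        n: factory.probabilities(int(branch_classes[n]), float(tree.lengths[n]))
        for n in range(tree.n_nodes)
        if n != tree.root
    }
    aligned = alignment.reordered(tree.taxa)
    internal = [n for n in range(tree.n_nodes) if n >= tree.n_taxa]
    pi = model.codon_frequencies
    n_states = len(SENSE_CODONS)
    total = 0.0
    for site in range(aligned.n_sites):
        observed = aligned.codons[:, site]
        site_like = 0.0
        for assignment in itertools.product(range(n_states), repeat=len(internal)):
            state = dict(zip(internal, assignment))
            for leaf in range(tree.n_taxa):
                state[leaf] = int(observed[leaf])
            prob = pi[state[tree.root]]
            for node in range(tree.n_nodes):
                if node == tree.root:
                    continue
                prob *= pmats[node][state[tree.parent[node]], state[node]]
            site_like += prob
        total += np.log(site_like)
    return float(total)


def bar_bruteforce(forward, reverse, temperature) -> float:
    """Self-consistency root by coarse grid scan plus interval bisection,
    independent of the package's solver."""
    fw = np.asarray(forward, dtype=float)
    rv = np.asarray(reverse, dtype=float)
    kbt = kt(temperature)
    beta = 1.0 / kbt
    m = kbt * np.log(fw.size / rv.size)

    def resid(df):
        a = 1.0 / (1.0 + np.exp(np.clip(beta * (fw - df - m), -700, 700)))
        b = 1.0 / (1.0 + np.exp(np.clip(beta * (rv + df + m), -700, 700)))
        return a.sum() - b.sum()

    lo = min(fw.min(), rv.min()) - 50 * kbt
    hi = max(fw.max(), rv.max()) + 50 * kbt
    grid = np.linspace(lo, hi, 20001)
    vals = np.array([resid(g) for g in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size == 0:
        raise RuntimeError("no sign change on the scan grid")
    a, b = grid[sign_change[0]], grid[sign_change[0] + 1]
    for _ in range(200):
        mid = 0.5 * (a + b)
        if resid(a) * resid(mid) <= 0:
            b = mid
        else:
            a = mid
    return 0.5 * (a + b)


@pytest.fixture
def uniform_codon_model():
    def make(kappa=2.0, omegas=(0.2,)):
        pi = np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))
        return CodonSubstModel(kappa, dict(enumerate(omegas)), pi)

    return make


@pytest.fixture
def small_tree():
    return PhyloTree.from_newick("(A:0.1,B:0.2,(C:0.15,D:0.3):0.05);")
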