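"""Branch models of lineage-specific dN/dS and AIC model selection.

A branch hypothesis partitions the 2N-3 edges of an unrooted tree into omega
classes (class 0 is the background).  The canonical hypothesis ladder for a
focal duplicate lineage is:

* H0 — every branch shares one omega;
* H1 — the focal branch has its own omega, all others share one;
* H2/H3 — three classes (e.g. two focal lineages vs background, or focal
  lineage vs its clade vs background);
* H4 — every branch has its own omega.

Each hypothesis is fitted by maximum likelihood over branch lengths, kappa
and the class omegas (bounded L-BFGS-B with seeded multi-start), and models
are compared by AIC = 2k - 2 lnL with k = (2N-3) + 1 + (number of classes);
codon frequencies follow the empirical F3x4 convention and are not counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .codons import CodonAlignment, f3x4_frequencies
from .gy94 import CodonSubstModel, TransitionMatrixFactory
from .likelihood import PruningEngine
from .tree import PhyloTree

__all__ = [
    "BranchHypothesis",
    "single_ratio",
    "focal_branches",
    "free_ratios",
    "count_parameters",
    "CodonBranchModel",
    "CodonBranchModelResults",
    "ModelFitRecord",
    "aic",
    "model_selection",
]

_KAPPA_BOUNDS = (0.1, 20.0)
_OMEGA_BOUNDS = (1e-4, 10.0)
_LENGTH_BOUNDS = (0.0, 20.0)


@dataclass(frozen=True)
class BranchHypothesis:
    """A labelled partition of tree edges into omega classes.

    `groups` is an ordered tuple of selector collections; group g (1-based)
    assigns class g to every edge whose bipartition matches one of its
    selectors, where a selector is a set of taxon names identifying the edge
    (``{name}`` selects a terminal branch; a larger set selects the edge
    subtending exactly that clade).  Unselected edges form background class
    0.  ``free=True`` ignores `groups` and gives every edge its own class.
    """

    name: str
    groups: tuple[tuple[frozenset[str], ...], ...] = ()
    free: bool = False
    description: str = ""

    def n_classes(self, tree: PhyloTree) -> int:
        if self.free:
            return tree.n_edges
        return 1 + len(self.groups)

    def branch_classes(self, tree: PhyloTree) -> np.ndarray:
        """Class id per node (edge above the node; storage root gets 0)."""
        classes = np.zeros(tree.n_nodes, dtype=int)
        if self.free:
            for cls, edge in enumerate(tree.edges):
                classes[edge] = cls
            return classes
        all_taxa = set(tree.taxa)
        anchor = min(all_taxa)

        def canonical(names: frozenset[str]) -> frozenset[str]:
            return frozenset(all_taxa - names) if anchor in names else names

        edge_bip = {int(e): tree.edge_bipartition(int(e)) for e in tree.edges}
        for gi, selectors in enumerate(self.groups, start=1):
            for sel in selectors:
                sel = frozenset(sel)
                unknown = sel - all_taxa
                if unknown:
                    raise ValueError(f"unknown taxa in selector: {sorted(unknown)}")
                want = canonical(sel)
                hits = [e for e, bip in edge_bip.items() if bip == want]
                if not hits:
                    raise ValueError(
                        f"hypothesis {self.name!r}: no edge matches selector "
                        f"{sorted(sel)}"
                    )
                for e in hits:
                    if classes[e] != 0:
                        raise ValueError(
                            f"hypothesis {self.name!r}: edge for {sorted(sel)} "
                            "assigned to two groups"
                        )
                    classes[e] = gi
        return classes


def single_ratio(name: str = "H0") -> BranchHypothesis:
    """One omega shared by every branch."""
    return BranchHypothesis(name, (), description="one ratio for all branches")


def focal_branches(
    groups: Sequence[Iterable[Iterable[str]]], name: str = "H1", description: str = ""
) -> BranchHypothesis:
    """Hypothesis from explicit selector groups (see `BranchHypothesis`).

    ``focal_branches([[{"trout_a2"}]])`` gives the classic two-ratio model:
    the terminal branch of ``trout_a2`` vs all other branches.
    """
    packed = tuple(
        tuple(frozenset(sel) for sel in group) for group in groups
    )
    return BranchHypothesis(name, packed, description=description)


def free_ratios(name: str = "H4") -> BranchHypothesis:
    """Every branch gets its own omega."""
    return BranchHypothesis(name, free=True, description="every branch its own ratio")


def count_parameters(tree: PhyloTree, hypothesis: BranchHypothesis) -> int:
    """Number of free parameters: (2N-3 branch lengths) + kappa + omegas.

    Codon frequencies follow the empirical-frequency convention and are not
    counted.  Requires a fully resolved unrooted tree.
    """
    if not tree.is_fully_resolved_unrooted():
        raise ValueError("tree must be fully resolved and unrooted")
    return tree.n_edges + 1 + hypothesis.n_classes(tree)


def aic(lnL: float, k: int) -> float:
    """Akaike information criterion, 2k - 2 lnL (full precision)."""
    if not np.isfinite(lnL):
        raise ValueError("lnL must be finite")
    return 2.0 * k - 2.0 * lnL


@dataclass(frozen=True)
class ModelFitRecord:
    """A minimal fitted-model record, e.g. transcribed from a published table."""

    hypothesis: str
    lnL: float
    k: int
    data_signature: object | None = None

    @property
    def aic(self) -> float:
        return aic(self.lnL, self.k)


@dataclass
class CodonBranchModelResults:
    """Maximum-likelihood fit of one branch hypothesis.

    Attributes mirror the usual model-selection table: `lnL`, `k`, `aic`,
    plus the parameter estimates themselves.
    """

    hypothesis: str
    lnL: float
    k: int
    kappa: float
    omega_by_class: dict[int, float]
    branch_lengths: np.ndarray
    tree: PhyloTree
    converged: bool
    n_starts: int
    start_logliks: tuple[float, ...]
    model: "CodonBranchModel"
    data_signature: object | None = None

    @property
    def aic(self) -> float:
        return aic(self.lnL, self.k)

    @property
    def aic_reported(self) -> int:
        """AIC rounded to the nearest integer (reporting convention)."""
        return int(round(self.aic))

    def fitted_tree(self) -> PhyloTree:
        return self.tree.with_lengths(self.branch_lengths)

    def summary(self) -> str:
        lines = [
            f"Codon branch model: {self.hypothesis}",
            "=" * 46,
            f"taxa:        {self.tree.n_taxa}    sites: {self.model.engine.n_sites}"
            f" ({self.model.engine.n_patterns} patterns)",
            f"parameters:  k = {self.k}",
            f"lnL:         {self.lnL:.4f}",
            f"AIC:         {self.aic:.4f}  (reported {self.aic_reported})",
            f"kappa:       {self.kappa:.4f}",
        ]
        for cls in sorted(self.omega_by_class):
            label = "background" if cls == 0 else f"class {cls}"
            lines.append(f"omega[{label}]: {self.omega_by_class[cls]:.4f}")
        if not self.converged:
            lines.append("WARNING: optimizer did not report convergence")
        return "\n".join(lines)


class CodonBranchModel:
    """GY94-family branch model bound to one alignment, tree and hypothesis.

    Parameters
    ----------
    alignment : CodonAlignment
        Coding alignment; columns with gaps or ambiguity are removed.
    tree : PhyloTree
        Fully resolved unrooted topology; its branch lengths seed the
        optimizer (typically neighbor-joining estimates).
    hypothesis : BranchHypothesis
        Partition of edges into omega classes.
    codon_frequencies : ndarray, optional
        Stationary frequencies; empirical F3x4 from the alignment by default.
    """

    def __init__(
        self,
        alignment: CodonAlignment,
        tree: PhyloTree,
        hypothesis: BranchHypothesis,
        codon_frequencies: np.ndarray | None = None,
    ) -> None:
        if not tree.is_fully_resolved_unrooted():
            raise ValueError("tree must be fully resolved and unrooted")
        clean = alignment.drop_incomplete_columns()
        if clean.n_sites == 0:
            raise ValueError("no complete codon columns to analyze")
        self.alignment = clean
        self.tree = tree
        self.hypothesis = hypothesis
        if codon_frequencies is None:
            pi = f3x4_frequencies(clean)
        else:
            pi = np.asarray(codon_frequencies, dtype=float)
        # transition matrices need strictly positive frequencies
        pi = np.maximum(pi, 1e-8)
        self.codon_frequencies = pi / pi.sum()
        self.branch_classes = hypothesis.branch_classes(tree)
        self.n_classes = hypothesis.n_classes(tree)
        self.engine = PruningEngine(clean, tree)
        self._edges = self.tree.edges

    @property
    def k(self) -> int:
        return count_parameters(self.tree, self.hypothesis)

    # -- objective -------------------------------------------------------
    def _unpack(self, x: np.ndarray):
        n_e = self._edges.size
        lengths = np.zeros(self.tree.n_nodes)
        lengths[self._edges] = x[:n_e]
        kappa = x[n_e]
        omegas = {c: x[n_e + 1 + c] for c in range(self.n_classes)}
        return lengths, kappa, omegas

    def loglik(self, lengths: np.ndarray, kappa: float, omegas: dict[int, float]) -> float:
        model = CodonSubstModel(kappa, omegas, self.codon_frequencies)
        factory = TransitionMatrixFactory(model)
        return self.engine.loglik(
            self.codon_frequencies, factory, self.branch_classes, lengths
        )

    def _negloglik(self, x: np.ndarray) -> float:
        lengths, kappa, omegas = self._unpack(x)
        try:
            return -self.loglik(lengths, kappa, omegas)
        except FloatingPointError:
            return 1e12

    # -- fitting ---------------------------------------------------------
    def fit(
        self,
        start_kappa: float = 2.0,
        start_omega: float = 0.2,
        n_starts: int = 3,
        seed: int = 0,
        starts: Sequence[tuple[float, dict[int, float]]] | None = None,
        maxiter: int = 1000,
    ) -> CodonBranchModelResults:
        """Maximize lnL over branch lengths, kappa and class omegas.

        Multi-start: the first start uses (`start_kappa`, `start_omega`);
        the remaining `n_starts - 1` apply seeded log-normal jitter to kappa
        and the omegas.  Explicit `starts` (list of ``(kappa, omega_by_class)``)
        override the defaults.  Branch lengths always start from the tree's
        lengths (floored at 1e-4).
        """
        rng = np.random.default_rng(seed)
        if starts is None:
            starts_list = [(start_kappa, {c: start_omega for c in range(self.n_classes)})]
            for _ in range(n_starts - 1):
                kap = float(np.clip(start_kappa * np.exp(rng.normal(0, 0.5)),
                                    *_KAPPA_BOUNDS))
                oms = {
                    c: float(np.clip(start_omega * np.exp(rng.normal(0, 0.7)),
                                     *_OMEGA_BOUNDS))
                    for c in range(self.n_classes)
                }
                starts_list.append((kap, oms))
        else:
            starts_list = [(k, dict(o)) for k, o in starts]

        n_e = self._edges.size
        init_lengths = np.maximum(self.tree.lengths[self._edges], 1e-4)
        bounds = (
            [_LENGTH_BOUNDS] * n_e
            + [_KAPPA_BOUNDS]
            + [_OMEGA_BOUNDS] * self.n_classes
        )

        best = None
        start_logliks = []
        any_converged = False
        for kap, oms in starts_list:
            x0 = np.concatenate(
                [init_lengths, [kap], [oms[c] for c in range(self.n_classes)]]
            )
            res = minimize(
                self._negloglik,
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-6},
            )
            start_logliks.append(-res.fun)
            any_converged = any_converged or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        if not any_converged:
            warnings.warn(
                "branch-model optimizer did not converge from any start; "
                "returning best-found values",
                stacklevel=2,
            )
        lengths, kappa, omegas = self._unpack(best.x)
        return CodonBranchModelResults(
            hypothesis=self.hypothesis.name,
            lnL=-float(best.fun),
            k=self.k,
            kappa=float(kappa),
            omega_by_class={c: float(w) for c, w in omegas.items()},
            branch_lengths=lengths,
            tree=self.tree,
            converged=any_converged,
            n_starts=len(starts_list),
            start_logliks=tuple(start_logliks),
            model=self,
            data_signature=self.engine.data_signature(),
        )


def model_selection(fits: Sequence) -> tuple[pd.DataFrame, object]:
    """Rank fitted models by AIC; returns (table, best fit).

    Accepts `CodonBranchModelResults` and/or `ModelFitRecord` objects.  All
    fits must be on the same data (records without a data signature are not
    checked).  Ties on AIC are broken by smaller k, then hypothesis id.
    The table reports AIC rounded to the nearest integer; ranking uses full
    precision.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("model selection needs at least two fitted models")
    signatures = {
        f.data_signature for f in fits if getattr(f, "data_signature", None) is not None
    }
    if len(signatures) > 1:
        raise ValueError("fits are not all on the same alignment")
    order = sorted(fits, key=lambda f: (f.aic, f.k, f.hypothesis))
    best = order[0]
    df = pd.DataFrame(
        {
            "hypothesis": [f.hypothesis for f in order],
            "k": [f.k for f in order],
            "lnL": [f.lnL for f in order],
            "AIC": [int(round(f.aic)) for f in order],
            "best": [f is best for f in order],
        }
    )
    return df, best
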