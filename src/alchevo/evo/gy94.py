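"""Goldman-Yang-style codon substitution model (branch variant).

The instantaneous rate from codon i to codon j (i != j) is

    q_ij = 0                      if i and j differ at more than one position
         = pi_j                   synonymous transversion
         = kappa * pi_j           synonymous transition
         = omega * pi_j           nonsynonymous transversion
         = omega * kappa * pi_j   nonsynonymous transition

over the 61 sense codons of the standard code, with kappa the
transition/transversion rate ratio, omega = dN/dS, and pi the stationary
codon frequencies.  Rows sum to zero and the generator is scaled so the
expected substitution rate at stationarity, -sum_i pi_i q_ii, is 1, making
branch lengths expected substitutions per codon.  In branch models each
branch class has its own omega (kappa and pi are shared).

The chain is time-reversible (pi_i q_ij = pi_j q_ji), so transition matrices
exp(Q t) are computed by symmetrizing with pi^(1/2) and diagonalizing once
per (kappa, omega) combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .codons import CODON_AMINO_ACIDS, SENSE_CODONS

__all__ = ["CodonSubstModel", "gy94_rate_matrix", "TransitionMatrixFactory"]

_N = len(SENSE_CODONS)
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _single_change_masks() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean (61, 61) masks: single-nucleotide change, transition,
    nonsynonymous."""
    single = np.zeros((_N, _N), dtype=bool)
    is_ts = np.zeros((_N, _N), dtype=bool)
    nonsyn = np.zeros((_N, _N), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            is_ts[i, j] = diffs[0] in _TRANSITIONS
            nonsyn[i, j] = CODON_AMINO_ACIDS[i] != CODON_AMINO_ACIDS[j]
    return single, is_ts, nonsyn

_SINGLE, _IS_TS, _NONSYN = _single_change_masks()


@dataclass(frozen=True)
class CodonSubstModel:
    """Parameters of a branch codon model.

    Attributes
    ----------
    kappa : float
        Transition/transversion rate ratio (> 0).
    omega_by_class : mapping of int -> float
        dN/dS per branch class (>= 0); class ids must be contiguous from 0.
    codon_frequencies : ndarray of shape (61,)
        Stationary frequencies over the sense codons (simplex).
    """

    kappa: float
    omega_by_class: Mapping[int, float]
    codon_frequencies: np.ndarray

    def __init__(self, kappa, omega_by_class, codon_frequencies):
        if not np.isfinite(kappa) or kappa <= 0:
            raise ValueError("kappa must be positive and finite")
        omega_by_class = dict(omega_by_class)
        if sorted(omega_by_class) != list(range(len(omega_by_class))):
            raise ValueError("omega class ids must be contiguous from 0")
        for w in omega_by_class.values():
            if not np.isfinite(w) or w < 0:
                raise ValueError("omega values must be finite and >= 0")
        pi = np.asarray(codon_frequencies, dtype=float)
        if pi.shape != (_N,):
            raise ValueError(f"codon_frequencies must have shape ({_N},)")
        if (pi < 0).any() or not np.isclose(pi.sum(), 1.0):
            raise ValueError("codon_frequencies must be a simplex")
        object.__setattr__(self, "kappa", float(kappa))
        object.__setattr__(self, "omega_by_class", omega_by_class)
        object.__setattr__(self, "codon_frequencies", pi)

    @property
    def n_classes(self) -> int:
        return len(self.omega_by_class)


def gy94_rate_matrix(model: CodonSubstModel, class_id: int = 0) -> np.ndarray:
    """Scaled 61x61 generator for one branch class (mean rate 1)."""
    if class_id not in model.omega_by_class:
        raise KeyError(f"no omega for branch class {class_id}")
    return _rate_matrix(model.codon_frequencies, model.kappa,
                        model.omega_by_class[class_id])


def _rate_matrix(pi: np.ndarray, kappa: float, omega: float) -> np.ndarray:
    q = np.where(_SINGLE, np.tile(pi, (_N, 1)), 0.0)
    q = q * np.where(_IS_TS, kappa, 1.0) * np.where(_NONSYN, omega, 1.0)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = -float(pi @ np.diag(q))
    if mean_rate <= 0:
        raise ValueError("degenerate model: zero mean substitution rate")
    return q / mean_rate


class TransitionMatrixFactory:
    """Cache of spectral decompositions for fast exp(Q t) evaluation.

    One eigendecomposition is done per branch class; `probabilities(class_id,
    t)` then costs two small matrix products.  Entries are clipped into
    [0, 1] to guard against round-off.
    """

    def __init__(self, model: CodonSubstModel) -> None:
        self.model = model
        pi = model.codon_frequencies
        if (pi <= 0).any():
            raise ValueError(
                "transition matrices require strictly positive frequencies"
            )
        sqrt_pi = np.sqrt(pi)
        self._decomp: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for cls in model.omega_by_class:
            q = gy94_rate_matrix(model, cls)
            sym = (sqrt_pi[:, None]) * q / sqrt_pi[None, :]
            evals, evecs = np.linalg.eigh(0.5 * (sym + sym.T))
            left = evecs.T * sqrt_pi[None, :]
            right = evecs / sqrt_pi[:, None]
            self._decomp[cls] = (evals, right, left)

    def probabilities(self, class_id: int, t: float) -> np.ndarray:
        """Transition probability matrix exp(Q_class * t)."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        evals, right, left = self._decomp[class_id]
        p = (right * np.exp(evals * t)) @ left
        return np.clip(p, 0.0, 1.0)
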