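"""Bennett acceptance ratio (BAR) free-energy estimation.

For forward works W_F (A -> B) and reverse works W_R (B -> A) the BAR estimate
dF solves the self-consistency equation

    sum_i f(beta (W_F,i - dF - M)) = sum_j f(beta (W_R,j + dF + M)),

with f the Fermi function 1/(1+e^x), beta = 1/(k_B T) and M = k_B T ln(nF/nR).
This is the minimum-variance two-state estimator; the equation follows from
the Crooks fluctuation relation.  A ladder of intermediate states (e.g. a
sequence of restraint force constants) is handled by summing adjacent-pair
estimates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit

from ..constants import kt
from .series import FreeEnergyEstimate, WorkSampleSet

__all__ = ["BennettAcceptanceRatio", "BARResults", "bar_pair", "bar_ladder"]

_TOL = 1e-10  # kJ/mol, on the bracket width


class BARConvergenceWarning(UserWarning):
    """Raised when the work distributions barely overlap and the bracket had
    to be widened to find a sign change."""


def _fermi(x: np.ndarray) -> np.ndarray:
    # 1/(1+e^x), numerically stable
    return expit(-x)


def _residual(df: float, wf: np.ndarray, wr: np.ndarray, beta: float, m: float) -> float:
    # strictly increasing in df
    return float(
        _fermi(beta * (wf - df - m)).sum() - _fermi(beta * (wr + df + m)).sum()
    )


def _solve_bar(wf: np.ndarray, wr: np.ndarray, beta: float, m: float,
               lo: float, hi: float) -> float:
    """Deterministic bisection for the self-consistency root."""
    rlo = _residual(lo, wf, wr, beta, m)
    rhi = _residual(hi, wf, wr, beta, m)
    widened = False
    span = hi - lo
    while rlo * rhi > 0 and span < 1e8:
        lo -= span
        hi += span
        span = hi - lo
        rlo = _residual(lo, wf, wr, beta, m)
        rhi = _residual(hi, wf, wr, beta, m)
        widened = True
    if widened:
        warnings.warn(
            "BAR work distributions have poor overlap; bracket was widened",
            BARConvergenceWarning,
            stacklevel=3,
        )
    if rlo * rhi > 0:
        # no sign change even after widening: return endpoint with smaller |residual|
        return lo if abs(rlo) < abs(rhi) else hi
    while hi - lo > _TOL:
        mid = 0.5 * (lo + hi)
        if _residual(mid, wf, wr, beta, m) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class BARResults:
    """Results of a BAR fit: the estimate plus per-rung breakdown."""

    estimate: FreeEnergyEstimate
    per_rung: tuple[FreeEnergyEstimate, ...]
    temperature: float

    @property
    def value(self) -> float:
        return self.estimate.value

    @property
    def stderr(self) -> float:
        return self.estimate.stderr

    def summary(self) -> str:
        lines = [
            "Bennett acceptance ratio",
            "=" * 42,
            f"temperature:  {self.temperature:.1f} K",
            f"rungs:        {len(self.per_rung)}",
        ]
        for i, est in enumerate(self.per_rung):
            lines.append(f"  rung {i:2d}:  {est.value:10.4f} +/- {est.stderr:.4f} kJ/mol")
        lines += [
            f"dG:           {self.value:10.4f} kJ/mol",
            f"stderr:       {self.stderr:10.4f} kJ/mol",
        ]
        return "\n".join(lines)


class BennettAcceptanceRatio:
    """BAR estimator over one state pair or an ordered ladder of pairs.

    Parameters
    ----------
    rungs : WorkSampleSet or sequence of WorkSampleSet
        One work-sample set per adjacent state pair, in ladder order.  All
        rungs must share a temperature.
    direction : str
        Recorded direction label for the combined estimate.
    """

    def __init__(
        self,
        rungs: WorkSampleSet | Sequence[WorkSampleSet],
        direction: str = "forward",
    ) -> None:
        if isinstance(rungs, WorkSampleSet):
            rungs = [rungs]
        rungs = list(rungs)
        if not rungs:
            raise ValueError("at least one rung is required")
        temps = {r.temperature for r in rungs}
        if len(temps) > 1:
            raise ValueError(f"rungs have mixed temperatures: {sorted(temps)}")
        self.rungs = rungs
        self.direction = direction
        self.temperature = rungs[0].temperature

    def _fit_pair(self, works: WorkSampleSet) -> FreeEnergyEstimate:
        wf, wr = works.forward_works, works.reverse_works
        kbt = kt(works.temperature)
        beta = 1.0 / kbt
        m = kbt * math.log(wf.size / wr.size)
        pooled = np.concatenate([wf, wr])
        lo = float(pooled.min()) - 10.0 * kbt
        hi = float(pooled.max()) + 10.0 * kbt
        df = _solve_bar(wf, wr, beta, m, lo, hi)
        # Bennett asymptotic variance from the Fermi weights at the solution
        ff = _fermi(beta * (wf - df - m))
        fr = _fermi(beta * (wr + df + m))
        var = kbt**2 * (
            (np.mean(ff**2) / np.mean(ff) ** 2 - 1.0) / wf.size
            + (np.mean(fr**2) / np.mean(fr) ** 2 - 1.0) / wr.size
        )
        stderr = math.sqrt(max(var, 0.0))
        return FreeEnergyEstimate(df, stderr, "BAR", self.direction)

    def fit(self) -> BARResults:
        per_rung = tuple(self._fit_pair(r) for r in self.rungs)
        value = sum(e.value for e in per_rung)
        stderr = math.sqrt(sum(e.stderr**2 for e in per_rung))
        est = FreeEnergyEstimate(value, stderr, "BAR", self.direction)
        return BARResults(est, per_rung, self.temperature)


def bar_pair(works: WorkSampleSet, direction: str = "forward") -> FreeEnergyEstimate:
    """BAR estimate between two states from forward/reverse works."""
    return BennettAcceptanceRatio(works, direction).fit().estimate


def bar_ladder(
    rungs: Sequence[WorkSampleSet], direction: str = "forward"
) -> FreeEnergyEstimate:
    """Sum of pairwise BAR estimates over an ordered ladder of state pairs;
    standard errors combine in quadrature."""
    return BennettAcceptanceRatio(rungs, direction).fit().estimate
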