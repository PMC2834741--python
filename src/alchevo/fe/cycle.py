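"""Thermodynamic-cycle assembly of an absolute binding free energy.

The binding free energy is decomposed along a closed cycle: restrain the bound
ligand, alchemically decouple its electrostatic and Lennard-Jones interactions
in the complex, release the restraints analytically into the standard-state
volume, recouple the ligand in solution, and correct for the simulation-vs-
standard volume.  The total is the signed sum of the leg free energies plus
the two analytic terms.

Running the alchemical legs in both directions (insertion: interactions turned
on; deletion: turned off) and comparing the assembled totals is the standard
convergence diagnostic — well-converged simulations give closely matching
totals either way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ..constants import DEFAULT_TEMPERATURE
from .series import FreeEnergyEstimate

__all__ = [
    "CycleLeg",
    "BindingCycle",
    "SimulationMetadata",
    "ConsistencyReport",
    "assemble_cycle",
    "consistency_check",
    "ALCHEMICAL_LEG_NAMES",
]

#: Canonical names of the four alchemical legs of a full decoupling cycle.
ALCHEMICAL_LEG_NAMES = (
    "elec-complex",
    "LJ-complex",
    "LJ-solution",
    "elec-solution",
)

_DIRECTIONS = {"insertion", "deletion"}


@dataclass(frozen=True)
class CycleLeg:
    """One named free-energy leg of a binding cycle."""

    name: str
    direction: str
    estimate: FreeEnergyEstimate

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"direction must be one of {_DIRECTIONS}")


@dataclass(frozen=True)
class SimulationMetadata:
    """Provenance record of engine settings; never used in computation."""

    lambda_schedules: Mapping[str, tuple[float, ...]] = field(default_factory=dict)
    soft_core: Mapping[str, float] = field(default_factory=dict)
    box_edge_nm: float | None = None
    n_waters: int | None = None
    engine_settings: str = ""


@dataclass(frozen=True)
class BindingCycle:
    """An assembled binding free energy.

    `sense` records which alchemical direction the cycle was declared in; a
    leg recorded in the declared sense contributes its value directly, a leg
    recorded in the opposite sense contributes negated.  The analytic
    restraint-release and volume-correction terms are interpreted as quoted in
    the insertion sense.
    """

    legs: tuple[CycleLeg, ...]
    restraint_release_dG: float
    volume_correction_dG: float
    total_dG: float
    total_stderr: float
    sense: str
    temperature: float
    label: str = ""
    metadata: SimulationMetadata | None = None

    def summary(self) -> str:
        lines = [
            f"Binding cycle: {self.label or '(unnamed)'}",
            "=" * 46,
            f"declared sense: {self.sense}",
            f"temperature:    {self.temperature:.1f} K",
        ]
        for leg in self.legs:
            sign = "+" if leg.direction == self.sense else "-"
            lines.append(
                f"  {leg.name:<16} ({leg.direction:<9}) {sign}{abs(leg.estimate.value):9.2f}"
                f"  (recorded {leg.estimate.value:9.2f} +/- {leg.estimate.stderr:.2f})"
            )
        lines += [
            f"  {'restraint release':<28} {self.restraint_release_dG:9.2f}",
            f"  {'volume correction':<28} {self.volume_correction_dG:9.2f}",
            f"dG_bind:        {self.total_dG:9.2f} +/- {self.total_stderr:.2f} kJ/mol",
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class ConsistencyReport:
    """Insertion/deletion agreement diagnostic."""

    label: str
    dG_insertion: float
    dG_deletion: float
    discrepancy: float
    pooled_stderr: float
    threshold_stderr: float
    passed: bool

    def summary(self) -> str:
        verdict = "PASS" if self.passed else "FAIL"
        return (
            f"Insertion/deletion consistency [{self.label}]: "
            f"|{self.dG_insertion:.2f} - ({self.dG_deletion:.2f})| = "
            f"{self.discrepancy:.2f} kJ/mol, pooled stderr {self.pooled_stderr:.2f}, "
            f"threshold {self.threshold_stderr:g} stderr -> {verdict}"
        )


def assemble_cycle(
    legs: Iterable[CycleLeg],
    restraint_release_dG: float,
    volume_correction_dG: float,
    sense: str = "insertion",
    temperature: float = DEFAULT_TEMPERATURE,
    label: str = "",
    required: Sequence[str] | None = None,
    metadata: SimulationMetadata | None = None,
) -> BindingCycle:
    """Sum the cycle: signed legs + restraint release + volume correction.

    Parameters
    ----------
    legs : iterable of CycleLeg
        Uniquely named component legs.  A leg whose recorded direction matches
        the declared `sense` contributes its value; the opposite direction
        contributes the negated value.
    restraint_release_dG, volume_correction_dG : float
        Analytic terms in kJ/mol, quoted in the insertion sense; they are
        negated when the cycle is declared in the deletion sense.
    sense : {"insertion", "deletion"}
        Declared direction of the assembled cycle.
    required : sequence of str, optional
        Leg names that must be present (e.g. `ALCHEMICAL_LEG_NAMES` for a full
        four-leg decoupling cycle); missing names raise.
    """
    if sense not in _DIRECTIONS:
        raise ValueError(f"sense must be one of {_DIRECTIONS}")
    legs = tuple(legs)
    names = [leg.name for leg in legs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate leg names: {dupes}")
    if required is not None:
        missing = sorted(set(required) - set(names))
        if missing:
            raise ValueError(f"cycle is missing required legs: {missing}")
    flip = 1.0 if sense == "insertion" else -1.0
    total = flip * (restraint_release_dG + volume_correction_dG)
    var = 0.0
    for leg in legs:
        sign = 1.0 if leg.direction == sense else -1.0
        total += sign * leg.estimate.value
        var += leg.estimate.stderr**2
    return BindingCycle(
        legs=legs,
        restraint_release_dG=restraint_release_dG,
        volume_correction_dG=volume_correction_dG,
        total_dG=total,
        total_stderr=math.sqrt(var),
        sense=sense,
        temperature=temperature,
        label=label,
        metadata=metadata,
    )


def consistency_check(
    cycle_ins: BindingCycle,
    cycle_del: BindingCycle,
    threshold_stderr: float = 2.0,
) -> ConsistencyReport:
    """Compare totals of the same cycle assembled in both directions.

    Reports the absolute discrepancy, the pooled standard error, and a pass
    flag (discrepancy <= `threshold_stderr` pooled standard errors).  Both
    cycles must carry the same label (same receptor/ligand system).
    """
    if cycle_ins.label != cycle_del.label:
        raise ValueError(
            f"cycle labels differ: {cycle_ins.label!r} vs {cycle_del.label!r}"
        )

    # express both totals in the insertion sense before comparing
    def _as_insertion(c: BindingCycle) -> float:
        return c.total_dG if c.sense == "insertion" else -c.total_dG

    disc = abs(_as_insertion(cycle_ins) - _as_insertion(cycle_del))
    pooled = math.sqrt(cycle_ins.total_stderr**2 + cycle_del.total_stderr**2)
    passed = disc <= threshold_stderr * pooled
    return ConsistencyReport(
        label=cycle_ins.label,
        dG_insertion=_as_insertion(cycle_ins),
        dG_deletion=_as_insertion(cycle_del),
        discrepancy=disc,
        pooled_stderr=pooled,
        threshold_stderr=threshold_stderr,
        passed=passed,
    )
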