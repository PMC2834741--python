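"""Analytic restraint-release and standard-state free-energy terms.

A decoupled ligand is held in the binding site by six harmonic restraints
acting on three anchor atoms in the ligand and three in the receptor: one
distance r, two angles (thetaA, thetaB) and three dihedrals (phiA, phiB,
phiC).  In the stiff-spring regime the free energy of releasing those
restraints into the standard-state volume V0 has the closed form

    dG = k_B T ln[ 8 pi^2 V0 sqrt(K_r K_tA K_tB K_pA K_pB K_pC)
                   / (r^2 sin(thetaA) sin(thetaB) (2 pi k_B T)^3) ]

which is positive for stiff force constants (releasing a tightly held ligand
into 1 M standard state gains entropy).  The standard-state volume correction
k_B T ln(V_sim / V0) accounts for the difference between the simulation box
volume and the 1 mol/L standard volume.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from ..constants import DEFAULT_TEMPERATURE, STANDARD_VOLUME, kt

__all__ = ["RestraintSpec", "boresch_restraint_release", "standard_state_correction"]


class FloppyRestraintWarning(UserWarning):
    """The stiff-spring approximation is questionable for this geometry."""


@dataclass(frozen=True)
class RestraintSpec:
    """Six-harmonic-restraint geometry and force constants.

    Distances in nm, angles in radians; force constants in kJ/mol/nm^2 for the
    distance and kJ/mol/rad^2 for angles and dihedrals.
    """

    r: float
    theta_a: float
    theta_b: float
    phi_a: float
    phi_b: float
    phi_c: float
    k_r: float
    k_theta_a: float
    k_theta_b: float
    k_phi_a: float
    k_phi_b: float
    k_phi_c: float
    temperature: float = DEFAULT_TEMPERATURE
    anchor_labels: tuple[str, ...] = ("L1", "L2", "L3", "R1", "R2", "R3")

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("equilibrium distance r must be positive")
        for name in ("theta_a", "theta_b"):
            v = getattr(self, name)
            if not 0.0 < v < math.pi:
                raise ValueError(f"{name} must lie strictly between 0 and pi")
        for name in self.force_constant_names():
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if len(self.anchor_labels) != 6:
            raise ValueError("six anchor atom labels are required")

    @staticmethod
    def force_constant_names() -> tuple[str, ...]:
        return ("k_r", "k_theta_a", "k_theta_b", "k_phi_a", "k_phi_b", "k_phi_c")

    def force_constants(self) -> tuple[float, ...]:
        return tuple(getattr(self, n) for n in self.force_constant_names())

    def scaled(self, factor: float) -> "RestraintSpec":
        """Copy with all six force constants multiplied by `factor`."""
        kwargs = {n: getattr(self, n) * factor for n in self.force_constant_names()}
        return RestraintSpec(
            self.r, self.theta_a, self.theta_b, self.phi_a, self.phi_b, self.phi_c,
            temperature=self.temperature, anchor_labels=self.anchor_labels, **kwargs,
        )


def _check_stiff(spec: RestraintSpec) -> None:
    kbt = kt(spec.temperature)
    floppy = []
    if math.sqrt(kbt / spec.k_r) > 0.25 * spec.r:
        floppy.append("r")
    for name, k in (("theta_a", spec.k_theta_a), ("theta_b", spec.k_theta_b)):
        theta = getattr(spec, name)
        if math.sqrt(kbt / k) > 0.25 * min(theta, math.pi - theta):
            floppy.append(name)
    for name in ("k_phi_a", "k_phi_b", "k_phi_c"):
        if math.sqrt(kbt / getattr(spec, name)) > 0.5:
            floppy.append(name)
    if floppy:
        warnings.warn(
            "stiff-spring approximation may be inaccurate for: " + ", ".join(floppy),
            FloppyRestraintWarning,
            stacklevel=3,
        )


def boresch_restraint_release(
    spec: RestraintSpec, standard_volume: float = STANDARD_VOLUME
) -> float:
    """Closed-form free energy (kJ/mol) of releasing the six harmonic
    restraints on a non-interacting ligand into `standard_volume` (nm^3).

    Positive for stiff restraints.  Raises for zero force constants (the
    harmonic approximation diverges) and degenerate angle geometry.
    """
    if any(k <= 0 for k in spec.force_constants()):
        raise ValueError("all six force constants must be positive")
    sin_a, sin_b = math.sin(spec.theta_a), math.sin(spec.theta_b)
    if sin_a <= 0 or sin_b <= 0:
        raise ValueError("sin(theta) must be positive for both angle restraints")
    if standard_volume <= 0:
        raise ValueError("standard volume must be positive")
    _check_stiff(spec)
    kbt = kt(spec.temperature)
    k_prod = math.prod(spec.force_constants())
    arg = (
        8.0 * math.pi**2 * standard_volume
        / (spec.r**2 * sin_a * sin_b)
        * math.sqrt(k_prod)
        / (2.0 * math.pi * kbt) ** 3
    )
    return kbt * math.log(arg)


def standard_state_correction(
    simulation_volume: float,
    standard_volume: float = STANDARD_VOLUME,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """k_B T ln(V_sim / V0) in kJ/mol; antisymmetric under swapping volumes.

    Positive when the simulation box is larger than the standard-state volume.
    """
    if simulation_volume <= 0 or standard_volume <= 0:
        raise ValueError("volumes must be positive")
    return kt(temperature) * math.log(simulation_volume / standard_volume)
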