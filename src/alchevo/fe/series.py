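"""Containers for sampled alchemical simulation output.

`LambdaSeries` holds per-lambda samples of dH/dlambda for one alchemical leg
(the input to thermodynamic integration); `WorkSampleSet` holds forward and
reverse work values between two states (the input to the Bennett acceptance
ratio); `FreeEnergyEstimate` is the common result record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ..constants import DEFAULT_TEMPERATURE

__all__ = [
    "LambdaSeries",
    "WorkSampleSet",
    "FreeEnergyEstimate",
    "discard_equilibration",
]


@dataclass(frozen=True)
class FreeEnergyEstimate:
    """A free-energy estimate with its standard error.

    Attributes
    ----------
    value : float
        Estimate in kJ/mol.
    stderr : float
        Standard error in kJ/mol (>= 0).
    method : str
        One of ``"TI-poly"``, ``"TI-trap"``, ``"BAR"``.
    direction : str
        One of ``"insertion"``, ``"deletion"``, ``"forward"``.
    """

    value: float
    stderr: float
    method: str
    direction: str = "forward"

    def __post_init__(self) -> None:
        if self.stderr < 0:
            raise ValueError("stderr must be non-negative")
        if self.method not in {"TI-poly", "TI-trap", "BAR"}:
            raise ValueError(f"unknown method {self.method!r}")
        if self.direction not in {"insertion", "deletion", "forward"}:
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class LambdaSeries:
    """Per-lambda samples of dH/dlambda for one alchemical leg.

    Parameters
    ----------
    lambda_values : sequence of float
        Coupling-parameter values in [0, 1], strictly increasing.
    dhdl_samples : sequence of 1-D arrays
        One array of dH/dlambda samples (kJ/mol) per lambda value.
    temperature : float
        Simulation temperature in kelvin.
    leg_label : str
        Free-text leg name, e.g. ``"LJ-complex-deletion"``.
    """

    lambda_values: tuple[float, ...]
    dhdl_samples: tuple[np.ndarray, ...]
    temperature: float = DEFAULT_TEMPERATURE
    leg_label: str = ""

    def __init__(
        self,
        lambda_values: Sequence[float],
        dhdl_samples: Sequence[Sequence[float]],
        temperature: float = DEFAULT_TEMPERATURE,
        leg_label: str = "",
    ) -> None:
        lam = tuple(float(x) for x in lambda_values)
        samples = tuple(np.asarray(s, dtype=float).ravel() for s in dhdl_samples)
        if len(lam) != len(samples):
            raise ValueError("lambda_values and dhdl_samples lengths differ")
        if any(not 0.0 <= x <= 1.0 for x in lam):
            raise ValueError("all lambda values must lie in [0, 1]")
        if any(b <= a for a, b in zip(lam, lam[1:])):
            raise ValueError("lambda values must be strictly increasing")
        if any(s.size < 1 for s in samples):
            raise ValueError("every lambda must have at least one sample")
        if temperature <= 0:
            raise ValueError("temperature must be positive")
        object.__setattr__(self, "lambda_values", lam)
        object.__setattr__(self, "dhdl_samples", samples)
        object.__setattr__(self, "temperature", float(temperature))
        object.__setattr__(self, "leg_label", leg_label)

    @property
    def n_lambdas(self) -> int:
        return len(self.lambda_values)

    def means(self) -> np.ndarray:
        """Per-lambda sample means of dH/dlambda (kJ/mol)."""
        return np.array([s.mean() for s in self.dhdl_samples])

    def stderrs(self) -> np.ndarray:
        """Per-lambda standard errors of the mean (0 where n < 2)."""
        out = np.zeros(self.n_lambdas)
        for i, s in enumerate(self.dhdl_samples):
            if s.size > 1:
                out[i] = s.std(ddof=1) / math.sqrt(s.size)
        return out


@dataclass(frozen=True)
class WorkSampleSet:
    """Forward and reverse work values between two adjacent states.

    Forward works are for the A -> B switch, reverse works for B -> A, both in
    kJ/mol at the shared `temperature`.
    """

    forward_works: np.ndarray
    reverse_works: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE
    state_labels: tuple[str, str] = ("A", "B")

    def __init__(
        self,
        forward_works: Sequence[float],
        reverse_works: Sequence[float],
        temperature: float = DEFAULT_TEMPERATURE,
        state_labels: Sequence[str] = ("A", "B"),
    ) -> None:
        fw = np.asarray(forward_works, dtype=float).ravel()
        rv = np.asarray(reverse_works, dtype=float).ravel()
        if fw.size == 0 or rv.size == 0:
            raise ValueError("both work lists must be non-empty")
        if temperature <= 0:
            raise ValueError("temperature must be positive")
        if len(state_labels) != 2:
            raise ValueError("state_labels must name exactly two states")
        object.__setattr__(self, "forward_works", fw)
        object.__setattr__(self, "reverse_works", rv)
        object.__setattr__(self, "temperature", float(temperature))
        object.__setattr__(self, "state_labels", (str(state_labels[0]), str(state_labels[1])))


def _truncate(samples: np.ndarray, fraction: float) -> np.ndarray:
    # keep ceil((1-fraction)*n): ties resolved toward keeping more data
    n = samples.size
    keep = math.ceil((1.0 - fraction) * n)
    if keep < 1:
        raise ValueError("equilibration discard would leave no samples")
    return samples[n - keep:]


def discard_equilibration(data, fraction: float):
    """Drop the initial `fraction` of every per-state sample list.

    Emulates discarding the first part of each simulation for equilibration.
    Keeps the last ``ceil((1-fraction)*n)`` samples of each list, preserving
    order. Works on `LambdaSeries` and `WorkSampleSet`; returns the same type.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    if fraction == 0.0:
        return data
    if isinstance(data, LambdaSeries):
        return LambdaSeries(
            data.lambda_values,
            [_truncate(s, fraction) for s in data.dhdl_samples],
            temperature=data.temperature,
            leg_label=data.leg_label,
        )
    if isinstance(data, WorkSampleSet):
        return WorkSampleSet(
            _truncate(data.forward_works, fraction),
            _truncate(data.reverse_works, fraction),
            temperature=data.temperature,
            state_labels=data.state_labels,
        )
    raise TypeError(f"unsupported input type {type(data).__name__}")
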