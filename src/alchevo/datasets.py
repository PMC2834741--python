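"""Bundled reference values from the rainbow trout estrogen receptor study.

These are published numbers for the binding of 17beta-estradiol (E2) to the
four *Oncorhynchus mykiss* estrogen receptor isoforms (ER-alpha1, ER-alpha2,
ER-beta1, ER-beta2) at 277 K, and for the accompanying lineage-specific
dN/dS analysis of the estrogen receptor ligand-binding domains.  The ER-alpha
pair arose in the recent salmonid whole-genome duplication (30 sequences in
the published alignment); the ER-beta pair dates to the older teleost
duplication.

Two kinds of entries are distinguished by the ``desk_scale`` flag:

* ``desk_scale=True`` — quantities this package recomputes from the other
  bundled numbers (cycle totals from components, AIC from (k, lnL)).
* ``desk_scale=False`` — quantities that required molecular dynamics
  simulations or GenBank sequence downloads to produce (the per-leg component
  free energies themselves, the real-data omega estimates, the sequence
  identity percentages).  They are consumed as *inputs* here and cannot be
  regenerated offline.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .constants import DEFAULT_TEMPERATURE

__all__ = [
    "binding_components",
    "binding_totals",
    "selection_models",
    "reference_omegas",
    "reference_identities",
    "ReferenceValue",
]

_ISOFORMS = ("ER-alpha1", "ER-alpha2", "ER-beta1", "ER-beta2")

# Insertion-direction component free energies (kJ/mol) per isoform at 277 K.
# Rows: electrostatic decoupling in complex, Lennard-Jones decoupling in
# complex, recoupling in solution.  The restraint-release and volume rows are
# shared across isoforms.  All values are MD-derived inputs (desk_scale=False).
_COMPONENTS_INSERTION = {
    "ER-alpha1": (-21.5, -146.7, 48.9),
    "ER-alpha2": (-27.6, -126.5, 49.9),
    "ER-beta1": (-31.4, -132.4, 52.4),
    "ER-beta2": (-24.2, -144.1, 49.9),
}
_RESTRAINT_RELEASE = 61.8
_VOLUME_CORRECTION = -6.8

# Published totals (kJ/mol), reproduced exactly by cycle assembly.
_TOTALS_INSERTION = {
    "ER-alpha1": -64.3,
    "ER-alpha2": -49.2,
    "ER-beta1": -56.4,
    "ER-beta2": -63.4,
}

# Branch-model fits for the ER-alpha ligand-binding domain (30 sequences):
# hypothesis label, parameter count k, log-likelihood, published AIC.
_SELECTION_ROWS = [
    ("H0", "one ratio for all branches", 59, -5645.4, 11409),
    ("H1", "trout ER-alpha2 branch vs all others", 60, -5641.7, 11403),
    ("H2", "trout ER-alpha1, trout ER-alpha2, others", 61, -5641.6, 11405),
    ("H3", "trout ER-alpha2, salmonid ER-alpha, others", 61, -5641.5, 11405),
    ("H4", "every branch its own ratio", 115, -5610.3, 11451),
]


@dataclass(frozen=True)
class ReferenceValue:
    """A published quantity with its provenance flag."""

    name: str
    value: float
    units: str
    desk_scale: bool
    note: str = ""


def binding_components(direction: str = "insertion") -> pd.DataFrame:
    """Published per-leg component free energies (kJ/mol) by isoform.

    These are MD-simulation outputs and enter the package only as inputs to
    the cycle assembler; only the insertion direction is bundled.
    """
    if direction != "insertion":
        raise ValueError("only the insertion-direction components are bundled")
    df = pd.DataFrame(
        _COMPONENTS_INSERTION,
        index=["elec-complex", "LJ-complex", "solution-recoupling"],
    )
    df.loc["restraint release"] = [_RESTRAINT_RELEASE] + [float("nan")] * 3
    df.loc["volume correction"] = [_VOLUME_CORRECTION] + [float("nan")] * 3
    return df


def binding_totals() -> pd.DataFrame:
    """Published binding free-energy totals (kJ/mol, insertion direction)."""
    return pd.DataFrame(
        {"dG_bind": _TOTALS_INSERTION, "temperature_K": DEFAULT_TEMPERATURE}
    )


def selection_models() -> pd.DataFrame:
    """Published branch-model fits (k, lnL, AIC) for the ER-alpha LBD."""
    return pd.DataFrame(
        _SELECTION_ROWS,
        columns=["hypothesis", "description", "k", "lnL", "AIC"],
    ).set_index("hypothesis")


def reference_omegas() -> tuple[ReferenceValue, ...]:
    """Published real-data dN/dS estimates (require GenBank data to refit)."""
    return (
        ReferenceValue(
            "omega_background_ERalpha", 0.09, "dN/dS", desk_scale=False,
            note="all ER-alpha branches except trout ER-alpha2, best model",
        ),
        ReferenceValue(
            "omega_trout_ERalpha2", 0.30, "dN/dS", desk_scale=False,
            note="focal trout ER-alpha2 branch, best model",
        ),
        ReferenceValue(
            "omega_ERbeta_single", 0.07, "dN/dS", desk_scale=False,
            note="single-ratio model over the ER-beta tree",
        ),
    )


def reference_identities() -> tuple[ReferenceValue, ...]:
    """Published pairwise sequence identities (require GenBank data)."""
    return (
        ReferenceValue(
            "identity_ERalpha1_ERalpha2", 75.4, "%", desk_scale=False,
            note="trout ER-alpha1 vs ER-alpha2 (recent salmonid duplicates)",
        ),
        ReferenceValue(
            "identity_ERbeta1_ERbeta2", 57.6, "%", desk_scale=False,
            note="trout ER-beta1 vs ER-beta2 (older teleost duplicates)",
        ),
    )
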