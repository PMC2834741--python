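"""Physical constants and default study conditions.

Units throughout the package: energies in kJ/mol, distances in nm, angles in
radians, temperatures in kelvin.
"""

#: Boltzmann constant in kJ/(mol K).
K_B = 0.0083144621

#: Default simulation temperature (K) — chosen to mimic the water temperature
#: of the rainbow trout's natural habitat.
DEFAULT_TEMPERATURE = 277.0

#: Standard-state volume in nm^3: the volume available to one molecule at a
#: concentration of 1 mol/L (1 / (N_A * 1 mol/L)).
STANDARD_VOLUME = 1.660539

#: Lennard-Jones coupling schedule: 21 uniformly spaced lambda values.
LJ_LAMBDA_SCHEDULE = tuple(round(0.05 * i, 2) for i in range(21))

#: Electrostatic coupling schedule: 11 lambda values clustered at the endpoints.
ELEC_LAMBDA_SCHEDULE = (
    0.0, 0.024, 0.095, 0.206, 0.345, 0.5, 0.655, 0.794, 0.905, 0.976, 1.0,
)

#: Harmonic restraint force-constant ladder (kJ/mol/nm^2 for the distance,
#: kJ/mol/rad^2 for angles and dihedrals) used to grow restraints in stages.
RESTRAINT_FORCE_CONSTANT_LADDER = (
    0.0, 25.0, 40.0, 60.0, 90.0, 150.0, 200.0, 300.0, 450.0, 700.0, 1000.0,
)


def kt(temperature: float) -> float:
    """Thermal energy k_B*T in kJ/mol."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return K_B * temperature
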