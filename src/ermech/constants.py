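"""Physical constants and default experimental conditions."""

#: Boltzmann constant, exact SI value [J/K].
K_B = 1.380649e-23

#: Default absolute temperature [K] (room temperature; consistent with the
#: kT <-> joule conversions used throughout, kT = 4.11e-21 J at 298 K).
DEFAULT_TEMPERATURE = 298.0

#: Default solvent (cytosol treated as water) viscosity [Pa s].
DEFAULT_VISCOSITY = 1.0e-3


def thermal_energy(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """k_B * T in joules."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return K_B * temperature
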