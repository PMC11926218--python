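"""Physical constants and unit conversions.

Internal unit system: lengths in nm, forces in pN, energies in pN*nm,
times in s, temperatures in K, concentrations in mol/L. Velocities are
accepted in um/s at API boundaries (the unit AFM instruments report) and
converted to nm/s internally.
"""

#: Boltzmann constant, pN*nm/K (1.380649e-23 J/K = 1.380649e-2 pN*nm/K).
K_BOLTZMANN_PN_NM = 1.380649e-2

#: Avogadro constant, 1/mol.
N_AVOGADRO = 6.02214076e23

#: Default laboratory temperature, K (ambient conditions).
DEFAULT_TEMPERATURE_K = 298.0

#: Litres per cubic nanometre.
LITRE_PER_NM3 = 1e-24

#: Nanometres per micrometre.
NM_PER_UM = 1e3


def thermal_energy(temperature_k: float) -> float:
    """Thermal energy k_B*T in pN*nm for a temperature in kelvin."""
    if temperature_k <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_k} K")
    return K_BOLTZMANN_PN_NM * temperature_k
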