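"""Physical constants and default thermodynamic settings.

Internal energy unit is kT at the reference temperature ``T_REF``; molar
free energies (e.g. the standard free energy of ATP hydrolysis) are
converted with the molar gas constant ``R``.
"""

K_B = 1.380649e-23
"""Boltzmann constant, J/K."""

H_PLANCK = 6.62607015e-34
"""Planck constant, J*s."""

R_GAS = 8.314
"""Molar gas constant, J/(mol*K)."""

T_REF = 298.15
"""Reference temperature (K) at which free-energy parameters are defined."""

DG0_HYDROLYSIS_KJ_MOL = -29.288
"""Standard Gibbs free energy of ATP -> ADP + Pi hydrolysis, kJ/mol."""


def attempt_frequency(temperature: float) -> float:
    """Eyring attempt frequency omega0 = kappa*kB*T/h with kappa = 1 (1/s)."""
    return K_B * temperature / H_PLANCK


def dg0_in_kt(temperature: float, dg0_kj_mol: float = DG0_HYDROLYSIS_KJ_MOL) -> float:
    """Standard hydrolysis free energy expressed in kT at ``temperature``."""
    return dg0_kj_mol * 1e3 / (R_GAS * temperature)
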