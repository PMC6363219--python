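"""Physical constants and unit conversions.

Internal unit system: energies in kcal/mol, lengths in angstrom (trajectory
coordinate) or nm (bulk kinetics), times in ns unless noted.
"""

#: Boltzmann constant in kcal/(mol K).
KB_KCAL = 0.0019872041

#: Default simulation temperature (K).
T_DEFAULT = 310.0

#: Thermal energy kBT at 310 K in kcal/mol.
KBT_310 = KB_KCAL * T_DEFAULT  # 0.61603...

#: Avogadro-based conversion: 1 mM = 6.022e-4 particles / nm^3.
MM_TO_PER_NM3 = 6.02214076e-4

#: 1 nm^3 in A^3.
NM3_IN_A3 = 1000.0


def kbt(temperature: float = T_DEFAULT) -> float:
    """Thermal energy kB*T in kcal/mol at the given temperature (K)."""
    return KB_KCAL * temperature


def mM_to_per_nm3(conc_mM: float) -> float:
    """Convert a molar concentration in mM to a number density in nm^-3."""
    return conc_mM * MM_TO_PER_NM3
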