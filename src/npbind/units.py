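"""Physical constants in the package's unit system (A, e, kcal/mol)."""

# Coulomb constant: energy of two unit charges 1 A apart, kcal*A/(mol*e^2)
COULOMB_CONSTANT = 332.0636

# Boltzmann constant times Avogadro's number, kcal/(mol*K)
KB_KCAL_MOL = 0.0019872041


def kt_kcal_mol(temperature: float = 300.0) -> float:
    """Thermal energy k_B*T in kcal/mol (0.5962 at 300 K)."""
    return KB_KCAL_MOL * temperature
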