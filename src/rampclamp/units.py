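"""Unit conventions and conversion constants.

Every public interface in this package uses one fixed unit system:
coordinates and distances in angstroms (Å), times in nanoseconds (ns),
forces in piconewtons (pN), energies in kcal/mol, masses in amu, charges
in elementary charges (e), temperatures in kelvin. All conversion
constants live here so no module carries its own factors.
"""

# Coulomb constant: E [kcal/mol] = COULOMB_K * q1 * q2 / r  (q in e, r in Å)
COULOMB_K = 332.0636

# Boltzmann constant in kcal/(mol*K)
KB = 0.0019872

# 1 pN * 1 Å of work, expressed in kcal/mol
PN_ANGSTROM_TO_KCAL_PER_MOL = 0.0143836

# force conversions between the mechanical (pN) and energetic (kcal/mol/Å)
# force units used by the Langevin engine
PN_TO_KCAL_PER_MOL_PER_A = PN_ANGSTROM_TO_KCAL_PER_MOL
KCAL_PER_MOL_PER_A_TO_PN = 1.0 / PN_ANGSTROM_TO_KCAL_PER_MOL


def spring_pn_per_nm_to_kcal(k_pn_per_nm: float) -> float:
    """Convert a spring stiffness from pN/nm to kcal/mol/Å²."""
    return k_pn_per_nm * 0.1 * PN_TO_KCAL_PER_MOL_PER_A


def spring_kcal_to_pn_per_nm(k_kcal: float) -> float:
    """Convert a spring stiffness from kcal/mol/Å² to pN/nm."""
    return k_kcal * 10.0 * KCAL_PER_MOL_PER_A_TO_PN
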