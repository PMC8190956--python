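"""Unit conventions and conversion constants.

All internal quantities are in Hartree atomic units (energy: Hartree,
length: Bohr, charge: elementary charge, polarizability: Bohr^3).
File I/O uses Ångström for coordinates; reported energies use kcal/mol.
"""

HARTREE_TO_KCAL = 627.509474
BOHR_TO_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM


def hartree_to_kcal(e_hartree: float) -> float:
    return e_hartree * HARTREE_TO_KCAL


def kcal_to_hartree(e_kcal: float) -> float:
    return e_kcal / HARTREE_TO_KCAL
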