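"""Physical constants and unit conversions.

Internal unit system is atomic units (bohr, electron charge) everywhere;
ångström and Debye appear only at the reporting boundary.
"""

BOHR_TO_ANGSTROM: float = 0.529177210903
ANGSTROM_TO_BOHR: float = 1.0 / BOHR_TO_ANGSTROM

#: 1 e·bohr in Debye
DEBYE_PER_E_BOHR: float = 2.541746473
#: 1 e·Å in Debye (≈ 4.8032047)
DEBYE_PER_E_ANGSTROM: float = DEBYE_PER_E_BOHR / BOHR_TO_ANGSTROM

#: Charge floor (e) below which a transition is declared to have no
#: appreciable charge transfer.
Q_FLOOR: float = 1e-8

#: Density floor (e·bohr⁻³) below which a voxel is treated as vacuum by the
#: grid basin assignment and falls back to nearest-nucleus labelling.
VACUUM_DENSITY: float = 1e-12

# Bragg–Slater empirical atomic radii in Å (Slater's 1964 table), used for
# the size adjustment of fuzzy cell weights.  Hydrogen uses the customary
# 0.35 Å value.  Elements not listed fall back to 1.0 Å.
BRAGG_SLATER_RADII_ANGSTROM = {
    "H": 0.35, "He": 0.28,
    "Li": 1.45, "Be": 1.05, "B": 0.85, "C": 0.70, "N": 0.65, "O": 0.60,
    "F": 0.50, "Ne": 0.45,
    "Na": 1.80, "Mg": 1.50, "Al": 1.25, "Si": 1.10, "P": 1.00, "S": 1.00,
    "Cl": 1.00, "Ar": 0.95,
    "K": 2.20, "Ca": 1.80, "Sc": 1.60, "Ti": 1.40, "V": 1.35, "Cr": 1.40,
    "Mn": 1.40, "Fe": 1.40, "Co": 1.35, "Ni": 1.35, "Cu": 1.35, "Zn": 1.35,
    "Ga": 1.30, "Ge": 1.25, "As": 1.15, "Se": 1.15, "Br": 1.15, "Kr": 1.10,
}
DEFAULT_BS_RADIUS_ANGSTROM: float = 1.0

# Element symbols indexed by atomic number (enough for the formats handled).
ELEMENT_SYMBOLS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr",
]


def symbol_for_z(z: int) -> str:
    if 0 < z < len(ELEMENT_SYMBOLS):
        return ELEMENT_SYMBOLS[z]
    return "X"


def z_for_symbol(symbol: str) -> int:
    s = symbol.strip().capitalize()
    try:
        return ELEMENT_SYMBOLS.index(s)
    except ValueError:
        return 1
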