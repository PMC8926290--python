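"""Physical constants and element data.

Internal length unit is the bohr; file I/O uses angstrom. CODATA-2018 values.
"""

# CODATA 2018 bohr radius in angstrom
BOHR_RADIUS_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_RADIUS_ANGSTROM

# 1 hartree in kcal/mol (CODATA 2018: E_h = 4.3597447222071e-18 J, N_A = 6.02214076e23)
HARTREE_TO_KCALMOL = 627.5094740631

_SYMBOLS = [
    "H", "He",
    "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar",
]

ATOMIC_NUMBERS = {s: i + 1 for i, s in enumerate(_SYMBOLS)}
ELEMENT_SYMBOLS = {z: s for s, z in ATOMIC_NUMBERS.items()}


def atomic_number(symbol: str) -> int:
    """Nuclear charge for an element symbol (case-insensitive)."""
    key = symbol.strip().capitalize()
    try:
        return ATOMIC_NUMBERS[key]
    except KeyError:
        raise KeyError(f"unknown element symbol: {symbol!r}") from None
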