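"""Static element data: atomic numbers, covalent and Bragg-Slater radii.

Covalent radii are the Cordero et al. (2008) single-bond values; Bragg-Slater
radii follow Slater (1964) with Becke's recommended 0.35 A for hydrogen.  Both
tables are stored in Angstrom and converted on access.
"""

from __future__ import annotations

BOHR_PER_ANGSTROM = 1.8897259886
ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM

#: speed of light in atomic units (defines the shielding prefactor 1/c^2)
SPEED_OF_LIGHT = 137.035999

# symbol -> (Z, covalent radius / A, Bragg-Slater radius / A)
_ELEMENTS: dict[str, tuple[int, float, float]] = {
    "H": (1, 0.31, 0.35),
    "He": (2, 0.28, 0.35),
    "Li": (3, 1.28, 1.45),
    "Be": (4, 0.96, 1.05),
    "B": (5, 0.84, 0.85),
    "C": (6, 0.76, 0.70),
    "N": (7, 0.71, 0.65),
    "O": (8, 0.66, 0.60),
    "F": (9, 0.57, 0.50),
    "Ne": (10, 0.58, 0.45),
    "Na": (11, 1.66, 1.80),
    "Mg": (12, 1.41, 1.50),
    "P": (15, 1.07, 1.00),
    "S": (16, 1.05, 1.00),
    "Cl": (17, 1.02, 1.00),
}

_BY_NUMBER = {z: sym for sym, (z, _, _) in _ELEMENTS.items()}


class ElementError(ValueError):
    """Raised for element symbols outside the supported table."""


def atomic_number(symbol: str) -> int:
    try:
        return _ELEMENTS[symbol.capitalize()][0]
    except KeyError:
        raise ElementError(f"unknown element symbol {symbol!r}") from None


def symbol_of(z: int) -> str:
    try:
        return _BY_NUMBER[z]
    except KeyError:
        raise ElementError(f"no element with atomic number {z}") from None


def covalent_radius(symbol: str) -> float:
    """Covalent radius in bohr."""
    try:
        return _ELEMENTS[symbol.capitalize()][1] * BOHR_PER_ANGSTROM
    except KeyError:
        raise ElementError(f"unknown element symbol {symbol!r}") from None


def bragg_slater_radius(symbol: str) -> float:
    """Bragg-Slater radius in bohr (used for Becke cell size adjustment)."""
    try:
        return _ELEMENTS[symbol.capitalize()][2] * BOHR_PER_ANGSTROM
    except KeyError:
        raise ElementError(f"unknown element symbol {symbol!r}") from None


def known_elements() -> tuple[str, ...]:
    return tuple(_ELEMENTS)
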