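"""Periodic-table constants for the elements occurring in ICRU body tissues.

Only the thirteen elements appearing in the ICRU 44/46 tissue compositions
are carried; anything else raises a KeyError at lookup time, which is the
desired behaviour for a dosimetry tool (an unknown element in a material
table is a data error, not something to silently accept).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Element:
    """A chemical element: symbol, atomic number Z and standard atomic mass A."""

    symbol: str
    Z: int
    A: float  # g/mol

    def __post_init__(self) -> None:
        if self.Z < 1:
            raise ValueError(f"atomic number must be >= 1, got {self.Z}")
        if self.A <= 0:
            raise ValueError(f"atomic mass must be > 0, got {self.A}")


#: Elements covering every ICRU 44/46 tissue (CIAAW 2021 standard atomic weights).
ELEMENTS: dict[str, Element] = {
    e.symbol: e
    for e in [
        Element("H", 1, 1.008),
        Element("C", 6, 12.011),
        Element("N", 7, 14.007),
        Element("O", 8, 15.999),
        Element("Na", 11, 22.990),
        Element("Mg", 12, 24.305),
        Element("P", 15, 30.974),
        Element("S", 16, 32.06),
        Element("Cl", 17, 35.45),
        Element("K", 19, 39.098),
        Element("Ca", 20, 40.078),
        Element("Fe", 26, 55.845),
        Element("I", 53, 126.904),
    ]
}

#: Full element names, as used by GATE/Geant4 material databases.
ELEMENT_NAMES: dict[str, str] = {
    "H": "Hydrogen",
    "C": "Carbon",
    "N": "Nitrogen",
    "O": "Oxygen",
    "Na": "Sodium",
    "Mg": "Magnesium",
    "P": "Phosphor",
    "S": "Sulfur",
    "Cl": "Chlorine",
    "K": "Potassium",
    "Ca": "Calcium",
    "Fe": "Iron",
    "I": "Iodine",
}


def get_element(symbol: str) -> Element:
    try:
        return ELEMENTS[symbol]
    except KeyError:
        raise KeyError(
            f"unknown element {symbol!r}; known: {sorted(ELEMENTS)}"
        ) from None
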