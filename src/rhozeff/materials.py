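"""Materials, elemental compositions and the effective atomic number.

At kV photon energies the photoelectric cross-section scales roughly as
Z^3-4, so both the mass density rho and the elemental make-up of a tissue
determine its absorbed dose.  The single descriptor used throughout this
package is the product rho * Z_eff, where Z_eff is a power-law weighted
mean atomic number of the mixture:

    Z_eff = (sum_i a_i Z_i**beta) ** (1/beta)

with a_i either the normalized mass fraction w_i, or the normalized
electron fraction w_i Z_i / A_i, of element i.  Different communities use
different (beta, weighting) conventions; :func:`calibrate_zeff_definition`
selects the convention that best reproduces a reference table of printed
Z_eff values, so the choice is explicit and reproducible rather than
hard-coded.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .errors import InvalidInputError
from .periodic import ELEMENTS, get_element

__all__ = [
    "ElementalComposition",
    "ZeffDefinition",
    "Material",
    "TissueTableEntry",
    "compute_zeff",
    "calibrate_zeff_definition",
    "rho_zeff",
    "make_material",
    "read_materials_csv",
    "write_materials_csv",
]

_SUM_TOL = 1e-6


@dataclass(frozen=True)
class ElementalComposition:
    """Mass fractions w_i of a mixture, keyed by element symbol.

    Fractions are renormalized to sum to exactly 1 at construction
    (reference tables round to 3-4 decimals, so raw sums are often
    0.999-1.001); after renormalization the sum is checked to 1e-6.
    """

    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.fractions:
            raise InvalidInputError("composition must contain at least one element")
        total = float(sum(self.fractions.values()))
        if total <= 0:
            raise InvalidInputError("mass fractions must sum to a positive value")
        normalized = {}
        for sym, w in self.fractions.items():
            get_element(sym)  # validates symbol
            if w < 0 or w > 1 + 1e-9:
                raise InvalidInputError(
                    f"mass fraction of {sym} out of [0, 1]: {w}"
                )
            if w > 0:
                normalized[sym] = float(w) / total
        if not normalized:
            raise InvalidInputError("composition has no element with positive fraction")
        object.__setattr__(self, "fractions", normalized)
        assert abs(sum(self.fractions.values()) - 1.0) < _SUM_TOL

    def __getitem__(self, symbol: str) -> float:
        return self.fractions.get(symbol, 0.0)

    def elements(self) -> list[str]:
        return sorted(self.fractions, key=lambda s: ELEMENTS[s].Z)


Weighting = Literal["mass-fraction", "electron-fraction"]


@dataclass(frozen=True)
class ZeffDefinition:
    """A (beta, weighting) convention for the effective atomic number."""

    exponent: float = 3.5
    weighting: Weighting = "mass-fraction"
    rms_deviation: float | None = None  # diagnostic from calibration, if any
    underdetermined: bool = False

    def __post_init__(self) -> None:
        if not 2.0 <= self.exponent <= 6.0:
            raise InvalidInputError(
                f"Z_eff exponent must be in [2, 6], got {self.exponent}"
            )
        if self.weighting not in ("mass-fraction", "electron-fraction"):
            raise InvalidInputError(f"unknown weighting {self.weighting!r}")


@dataclass(frozen=True)
class Material:
    """A named material: density, composition and derived Z_eff / rho*Z_eff."""

    name: str
    rho: float  # g/cm^3
    composition: ElementalComposition
    zeff: float
    rho_zeff: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise InvalidInputError(f"density must be > 0, got {self.rho}")
        if self.rho_zeff is None:
            object.__setattr__(self, "rho_zeff", self.rho * self.zeff)
        elif abs(self.rho_zeff - self.rho * self.zeff) > 1e-9 * max(
            1.0, abs(self.rho_zeff)
        ):
            raise InvalidInputError(
                f"{self.name}: rho_zeff={self.rho_zeff} inconsistent with "
                f"rho*zeff={self.rho * self.zeff}"
            )


@dataclass(frozen=True)
class TissueTableEntry:
    """A reference-table tissue: a Material plus the printed Z_eff and
    rho*Z_eff exactly as published (kept immutable for integrity tests;
    some printed products differ from round(rho*zeff, 2) by one unit in
    the last place because the publishers used unrounded inputs)."""

    material: Material
    printed_zeff: float
    printed_rho_zeff: float

    @property
    def name(self) -> str:
        return self.material.name

    @property
    def grid_rho_zeff(self) -> float:
        """Coordinate used when this entry anchors an interpolation."""
        return self.printed_rho_zeff


def _weights(composition: ElementalComposition, definition: ZeffDefinition):
    syms = list(composition.fractions)
    w = np.array([composition.fractions[s] for s in syms])
    Z = np.array([float(ELEMENTS[s].Z) for s in syms])
    if definition.weighting == "electron-fraction":
        A = np.array([ELEMENTS[s].A for s in syms])
        a = w * Z / A
    else:
        a = w
    return a / a.sum(), Z


def compute_zeff(
    composition: ElementalComposition, definition: ZeffDefinition | None = None
) -> float:
    """Effective atomic number of a mixture under a given convention.

    Z_eff = (sum a_i Z_i**beta)**(1/beta); always lies between the smallest
    and largest Z present in the mixture.
    """
    if definition is None:
        definition = ZeffDefinition()
    a, Z = _weights(composition, definition)
    beta = definition.exponent
    # log-sum-exp form keeps Z_i**beta well-conditioned up to iodine at beta=6
    return float(np.exp(np.log(np.sum(a * Z**beta)) / beta))


def rho_zeff(material: Material) -> float:
    """The rho * Z_eff product (g/cm^3) of a material."""
    return material.rho * material.zeff


def calibrate_zeff_definition(
    entries: Sequence[TissueTableEntry],
    beta_range: tuple[float, float] = (2.5, 5.0),
    beta_step: float = 0.01,
) -> ZeffDefinition:
    """Select the (beta, weighting) pair that best reproduces printed Z_eff.

    Grid search over beta in ``beta_range`` (inclusive, step ``beta_step``)
    crossed with both weightings, minimizing the RMS deviation between
    :func:`compute_zeff` on each entry's composition and its printed Z_eff.
    Ties break toward the smaller beta (mass-fraction first).  With fewer
    than 10 entries the returned definition is flagged underdetermined.
    """
    if not entries:
        raise InvalidInputError("need at least one table entry to calibrate")
    printed = np.array([e.printed_zeff for e in entries])
    betas = np.arange(
        beta_range[0], beta_range[1] + beta_step / 2, beta_step
    ).round(10)
    best: tuple[float, float, str] | None = None  # (rms, beta, weighting)
    for weighting in ("mass-fraction", "electron-fraction"):
        # precompute per-entry (a_i, Z_i) once per weighting
        pre = [
            _weights(e.material.composition, ZeffDefinition(3.0, weighting))
            for e in entries
        ]
        for beta in betas:
            z = np.array(
                [math.pow(float(np.sum(a * Z**beta)), 1.0 / beta) for a, Z in pre]
            )
            rms = float(np.sqrt(np.mean((z - printed) ** 2)))
            if best is None or rms < best[0] - 1e-12:
                best = (rms, float(beta), weighting)
    assert best is not None
    rms, beta, weighting = best
    return ZeffDefinition(
        exponent=beta,
        weighting=weighting,  # type: ignore[arg-type]
        rms_deviation=rms,
        underdetermined=len(entries) < 10,
    )


def make_material(
    name: str,
    rho: float,
    fractions: Mapping[str, float],
    definition: ZeffDefinition | None = None,
) -> Material:
    """Build a Material, deriving Z_eff from the composition."""
    comp = ElementalComposition(dict(fractions))
    return Material(name=name, rho=rho, composition=comp, zeff=compute_zeff(comp, definition))


# ---------------------------------------------------------------------------
# CSV interface: columns name, rho_g_cm3, then one column per element symbol.
# ---------------------------------------------------------------------------

def read_materials_csv(
    path: str | Path, definition: ZeffDefinition | None = None
) -> list[Material]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "name" not in reader.fieldnames:
            raise InvalidInputError(f"{path}: missing header with a 'name' column")
        if "rho_g_cm3" not in reader.fieldnames:
            raise InvalidInputError(f"{path}: missing 'rho_g_cm3' column")
        element_cols = [c for c in reader.fieldnames if c in ELEMENTS]
        if not element_cols:
            raise InvalidInputError(f"{path}: no element columns found")
        materials = []
        for row in reader:
            fractions = {
                c: float(row[c]) for c in element_cols if row.get(c) and float(row[c]) > 0
            }
            materials.append(
                make_material(row["name"], float(row["rho_g_cm3"]), fractions, definition)
            )
    return materials


def write_materials_csv(materials: Iterable[Material], path: str | Path) -> None:
    materials = list(materials)
    symbols = sorted(
        {s for m in materials for s in m.composition.fractions},
        key=lambda s: ELEMENTS[s].Z,
    )
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "rho_g_cm3", *symbols])
        for m in materials:
            writer.writerow(
                [m.name, f"{m.rho:.6g}"]
                + [f"{m.composition[s]:.6f}" for s in symbols]
            )
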