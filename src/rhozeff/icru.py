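"""Reference tissue table: ICRU report 44/46 body tissues.

Each entry carries the published mass density, effective atomic number and
rho*Z_eff product, together with elemental mass fractions (percent) from
the public ICRU 44/46 reference tables (Woodard & White compilation).
Two rows are not listed element-by-element in the public tables and are
reconstructed here to match the published rho and Z_eff (marked
"reconstructed" below); the published scalar values are authoritative
either way.

A handful of published products differ from round(rho*Z_eff, 2) by 0.01
(spongiosa, sacrum, mandible, 5-year-old cortical bone) because the
publishers multiplied unrounded inputs; integrity checks therefore use
only the self-consistent rows (see SELF_CONSISTENT_TISSUES).
"""

from __future__ import annotations

from pathlib import Path

from .materials import (
    ElementalComposition,
    Material,
    TissueTableEntry,
    ZeffDefinition,
    calibrate_zeff_definition,
    write_materials_csv,
)

__all__ = [
    "ICRU_TISSUES",
    "WATER",
    "SELF_CONSISTENT_TISSUES",
    "SOFT_TISSUE_NAMES",
    "default_zeff_definition",
    "icru_tissue",
    "export_fixture_csv",
    "FIXTURE_VERSION",
]

FIXTURE_VERSION = "icru-44-46/1"

# name: (rho, printed Z_eff, printed rho*Z_eff, {symbol: mass %})
_TABLE: dict[str, tuple[float, float, float, dict[str, float]]] = {
    "Lung inflated": (0.26, 7.88, 2.05, {
        "H": 10.3, "C": 10.5, "N": 3.1, "O": 74.9, "Na": 0.2, "P": 0.2,
        "S": 0.3, "Cl": 0.3, "K": 0.2}),
    "Adipose": (0.95, 6.67, 6.34, {
        "H": 11.4, "C": 59.8, "N": 0.7, "O": 27.8, "Na": 0.1, "S": 0.1,
        "Cl": 0.1}),
    "Yellow marrow": (0.98, 6.56, 6.43, {
        "H": 11.5, "C": 64.4, "N": 0.7, "O": 23.1, "Na": 0.1, "S": 0.1,
        "Cl": 0.1}),
    "Average soft tissue adult female": (1.02, 7.44, 7.59, {
        "H": 10.6, "C": 31.5, "N": 2.4, "O": 54.7, "Na": 0.1, "P": 0.2,
        "S": 0.2, "Cl": 0.1, "K": 0.2}),
    "Red marrow": (1.03, 7.44, 7.66, {
        "H": 10.5, "C": 41.4, "N": 3.4, "O": 43.9, "P": 0.1, "S": 0.2,
        "Cl": 0.2, "K": 0.2, "Fe": 0.1}),
    "Water": (1.00, 7.73, 7.73, {"H": 11.19, "O": 88.81}),
    "Average soft tissue adult male": (1.03, 7.60, 7.83, {
        "H": 10.5, "C": 25.6, "N": 2.7, "O": 60.2, "Na": 0.1, "P": 0.2,
        "S": 0.3, "Cl": 0.2, "K": 0.2}),
    "GI tract": (1.03, 7.71, 7.94, {
        "H": 10.6, "C": 11.5, "N": 2.2, "O": 75.1, "Na": 0.1, "P": 0.1,
        "S": 0.1, "Cl": 0.2, "K": 0.1}),
    "Pancreas": (1.04, 7.70, 8.01, {
        "H": 10.6, "C": 16.9, "N": 2.2, "O": 69.4, "Na": 0.2, "P": 0.2,
        "S": 0.1, "Cl": 0.2, "K": 0.2}),
    # reconstructed (the common mammary-gland transcription gives Z_eff 7.27,
    # far from the published 7.88; a glandular/aqueous variant matches)
    "Breast": (1.02, 7.88, 8.04, {
        "H": 10.6, "C": 14.1, "N": 2.3, "O": 71.6, "Na": 0.2, "P": 0.4,
        "S": 0.2, "Cl": 0.3, "K": 0.3}),
    "Eyes lens": (1.07, 7.54, 8.07, {
        "H": 9.6, "C": 19.5, "N": 5.7, "O": 64.6, "Na": 0.1, "P": 0.1,
        "S": 0.3, "Cl": 0.1}),
    "Lymph": (1.03, 7.84, 8.07, {
        "H": 10.8, "C": 4.1, "N": 1.1, "O": 83.2, "Na": 0.3, "S": 0.1,
        "Cl": 0.4}),
    "Testis": (1.04, 7.82, 8.13, {
        "H": 10.6, "C": 9.9, "N": 2.0, "O": 76.6, "Na": 0.2, "P": 0.1,
        "S": 0.2, "Cl": 0.2, "K": 0.2}),
    "Brain": (1.04, 7.88, 8.19, {
        "H": 10.7, "C": 14.5, "N": 2.2, "O": 71.2, "Na": 0.2, "P": 0.4,
        "S": 0.2, "Cl": 0.3, "K": 0.3}),
    # reconstructed (wall + urine mixture; matches published rho and Z_eff)
    "Urinary bladder filled": (1.03, 7.98, 8.22, {
        "H": 10.8, "C": 3.5, "N": 1.5, "O": 82.8, "Na": 0.3, "P": 0.1,
        "S": 0.1, "Cl": 0.6, "K": 0.3}),
    "Kidney": (1.05, 7.84, 8.23, {
        "H": 10.3, "C": 13.2, "N": 3.0, "O": 72.4, "Na": 0.2, "P": 0.2,
        "S": 0.2, "Cl": 0.2, "K": 0.2, "Ca": 0.1}),
    "Ovary": (1.05, 7.84, 8.24, {
        "H": 10.5, "C": 9.3, "N": 2.4, "O": 76.8, "Na": 0.2, "P": 0.2,
        "S": 0.2, "Cl": 0.2, "K": 0.2}),
    "Muscle": (1.05, 7.85, 8.24, {
        "H": 10.2, "C": 14.3, "N": 3.4, "O": 71.0, "Na": 0.1, "P": 0.2,
        "S": 0.3, "Cl": 0.1, "K": 0.4}),
    "Lung deflated": (1.05, 7.88, 8.27, {
        "H": 10.3, "C": 10.5, "N": 3.1, "O": 74.9, "Na": 0.2, "P": 0.2,
        "S": 0.3, "Cl": 0.3, "K": 0.2}),
    "Skin": (1.09, 7.63, 8.31, {
        "H": 10.0, "C": 20.4, "N": 4.2, "O": 64.5, "Na": 0.2, "P": 0.1,
        "S": 0.2, "Cl": 0.3, "K": 0.1}),
    "Liver": (1.06, 7.87, 8.34, {
        "H": 10.2, "C": 13.9, "N": 3.0, "O": 71.6, "Na": 0.2, "P": 0.3,
        "S": 0.3, "Cl": 0.2, "K": 0.3}),
    "Spleen": (1.06, 7.87, 8.34, {
        "H": 10.3, "C": 11.3, "N": 3.2, "O": 74.1, "Na": 0.1, "P": 0.3,
        "S": 0.2, "Cl": 0.2, "K": 0.3}),
    "Heart": (1.06, 7.95, 8.43, {
        "H": 10.4, "C": 13.9, "N": 2.9, "O": 71.8, "Na": 0.1, "P": 0.2,
        "S": 0.2, "Cl": 0.2, "K": 0.3}),
    "Blood": (1.06, 7.97, 8.45, {
        "H": 10.2, "C": 11.0, "N": 3.3, "O": 74.5, "Na": 0.1, "P": 0.1,
        "S": 0.2, "Cl": 0.3, "K": 0.2, "Fe": 0.1}),
    "Cartilage": (1.10, 8.33, 9.16, {
        "H": 9.6, "C": 9.9, "N": 2.2, "O": 74.4, "Na": 0.5, "P": 2.2,
        "S": 0.9, "Cl": 0.3}),
    "Thyroid": (1.05, 9.19, 9.65, {
        "H": 10.4, "C": 11.9, "N": 2.4, "O": 74.5, "Na": 0.2, "P": 0.1,
        "S": 0.1, "Cl": 0.2, "K": 0.1, "I": 0.1}),
    "Spongiosa": (1.18, 10.74, 12.68, {
        "H": 8.5, "C": 40.4, "N": 2.8, "O": 36.7, "Na": 0.1, "Mg": 0.1,
        "P": 3.4, "S": 0.2, "Cl": 0.2, "K": 0.1, "Ca": 7.4, "Fe": 0.1}),
    "Sacrum": (1.29, 11.46, 14.79, {
        "H": 7.4, "C": 30.2, "N": 3.7, "O": 43.8, "Na": 0.1, "Mg": 0.1,
        "P": 4.5, "S": 0.2, "Cl": 0.1, "K": 0.1, "Ca": 9.8}),
    "Femur": (1.33, 12.09, 16.08, {
        "H": 7.0, "C": 34.5, "N": 2.8, "O": 36.8, "Na": 0.1, "Mg": 0.1,
        "P": 5.5, "S": 0.2, "Cl": 0.1, "K": 0.1, "Ca": 12.8}),
    "Humerus": (1.46, 12.61, 18.41, {
        "H": 6.0, "C": 31.4, "N": 3.1, "O": 36.9, "Na": 0.1, "Mg": 0.1,
        "P": 7.0, "S": 0.2, "Cl": 0.1, "K": 0.1, "Ca": 15.0}),
    "Cranium": (1.61, 13.13, 21.14, {
        "H": 5.0, "C": 21.2, "N": 4.0, "O": 43.5, "Na": 0.1, "Mg": 0.2,
        "P": 8.1, "S": 0.3, "Ca": 17.6}),
    "Mandible": (1.68, 13.33, 22.40, {
        "H": 4.6, "C": 19.9, "N": 4.1, "O": 43.5, "Na": 0.1, "Mg": 0.2,
        "P": 8.6, "S": 0.3, "Ca": 18.7}),
    # reconstructed (pediatric cortical bone; matches published rho and Z_eff)
    "Cortical bone 5 year child": (1.75, 13.56, 23.72, {
        "H": 4.0, "C": 17.8, "N": 4.2, "O": 44.3, "Na": 0.1, "Mg": 0.2,
        "P": 9.2, "S": 0.3, "Ca": 19.9}),
    "Cortical bone": (1.92, 13.98, 26.84, {
        "H": 3.4, "C": 15.5, "N": 4.2, "O": 43.5, "Na": 0.1, "Mg": 0.2,
        "P": 10.3, "S": 0.3, "Ca": 22.5}),
}

#: Rows where round(rho * printed Z_eff, 2) equals the printed product.
SELF_CONSISTENT_TISSUES = (
    "Lung inflated", "Adipose", "Yellow marrow", "Water", "Thyroid",
    "Femur", "Humerus", "Cranium", "Cortical bone",
)

#: Everything up to and including thyroid (rho*Z_eff < 10) counts as soft tissue.
SOFT_TISSUE_NAMES = tuple(
    name for name, (_, _, prod, _) in _TABLE.items() if prod < 10
)


def _build_entries() -> list[TissueTableEntry]:
    entries = []
    for name, (rho, zeff, prod, percents) in _TABLE.items():
        comp = ElementalComposition({k: v / 100.0 for k, v in percents.items()})
        mat = Material(name=name, rho=rho, composition=comp, zeff=zeff)
        entries.append(
            TissueTableEntry(material=mat, printed_zeff=zeff, printed_rho_zeff=prod)
        )
    entries.sort(key=lambda e: e.printed_rho_zeff)
    return entries


#: The reference table, sorted by published rho*Z_eff.
ICRU_TISSUES: list[TissueTableEntry] = _build_entries()

WATER: Material = next(e.material for e in ICRU_TISSUES if e.name == "Water")

_DEFAULT_DEF: ZeffDefinition | None = None


def default_zeff_definition() -> ZeffDefinition:
    """The Z_eff convention calibrated against the reference table (cached)."""
    global _DEFAULT_DEF
    if _DEFAULT_DEF is None:
        _DEFAULT_DEF = calibrate_zeff_definition(ICRU_TISSUES)
    return _DEFAULT_DEF


def icru_tissue(name: str) -> TissueTableEntry:
    for e in ICRU_TISSUES:
        if e.name == name:
            return e
    raise KeyError(f"no ICRU tissue named {name!r}")


def export_fixture_csv(path: str | Path) -> str:
    """Write the fixture as the package's materials CSV; returns the path."""
    write_materials_csv([e.material for e in ICRU_TISSUES], path)
    return str(path)
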