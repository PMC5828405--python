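"""Dose-equivalent artificial tissue database.

Monte-Carlo studies of kV dose deposition show that two materials whose
rho*Z_eff values differ by no more than 0.2 g/cm^3 receive absorbed doses
within ~2% of each other.  A database of artificial tissues is therefore
generated on a 0.2-spaced rho*Z_eff lattice spanning the ICRU body-tissue
range (inflated lung ~2 to cortical bone ~27), each tissue built by
constrained interpolation of the two nearest ICRU reference tissues:

  i.   the target Z_eff is linearly interpolated between the anchors'
       published Z_eff values;
  ii.  elemental mass fractions are interpolated with the same weight;
  iii. Z_eff is recomputed from the interpolated fractions;
  iv.  while the recomputed Z_eff deviates from the target by more than 5%,
       0.001 of mass is transferred within a regime pair — carbon/oxygen in
       the soft-tissue regime (rho*Z_eff < 10), calcium/phosphorus in the
       bony regime — toward the higher-Z member if Z_eff is too low, toward
       the lower-Z member if too high;
  v.   the mass-fraction sum is restored to 1 through hydrogen (whose Z=1
       contribution to Z_eff is negligible);
  vi.  the density follows as rho = target rho*Z_eff / final Z_eff.

These materials carry no anatomical meaning; they are "dose-equivalent"
stand-ins whose spacing bounds the segmentation dose error.  Each tissue
finally receives the half-open HU interval centred on its predicted CBCT
number, so that the intervals tile the HU axis and voxel assignment is a
pure interval lookup.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import (
    AssignmentError,
    ConvergenceError,
    GenerationError,
    InvalidInputError,
    RangeError,
)
from .hu_calibration import CalibrationCurve, curve_from_json, curve_to_json, predict_hu
from .materials import (
    ElementalComposition,
    Material,
    TissueTableEntry,
    ZeffDefinition,
    compute_zeff,
)
from .periodic import ELEMENTS

__all__ = [
    "DEFAULT_GRID",
    "TissueGrid",
    "ArtificialTissue",
    "TissueDatabase",
    "interpolate_tissue",
    "build_database",
    "assign_hu_intervals",
    "database_to_json",
    "database_from_json",
    "database_to_csv",
]

#: Relative Z_eff tolerance triggering the iterative mass adjustment.
ZEFF_TOLERANCE = 0.05
#: Mass transferred per adjustment step.
ADJUST_STEP = 0.001
#: Iteration cap converting pathological targets into diagnosable errors.
MAX_ADJUST_ITERATIONS = 2000
#: rho*Z_eff below which the C/O pair is adjusted; Ca/P at or above it.
SOFT_BONE_BOUNDARY = 10.0

#: Floor of the first HU interval and ceiling of the last one.
HU_FLOOR = -1000.0
HU_CEILING = 32767.0


@dataclass(frozen=True)
class TissueGrid:
    """Regular rho*Z_eff lattice: start, stop inclusive, step."""

    start: float = 2.0
    stop: float = 26.8
    step: float = 0.2

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise InvalidInputError(f"grid start must be < stop: {self}")
        if self.step <= 0:
            raise InvalidInputError(f"grid step must be > 0: {self}")
        n = (self.stop - self.start) / self.step
        if abs(n - round(n)) > 1e-9:
            raise InvalidInputError(
                f"(stop - start)/step must be an integer, got {n} for {self}"
            )

    def values(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step))
        return self.start + self.step * np.arange(n + 1)

    def __len__(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1


#: 125 lattice values, 2.0 .. 26.8: the "from 2 up to 27 in steps of 0.2"
#: range spans 126 lattice points while the database holds 125 tissues, so
#: one endpoint is open; the lower endpoint is kept and cortical bone
#: (rho*Z_eff 26.84) still anchors the top of the range.
DEFAULT_GRID = TissueGrid(2.0, 26.8, 0.2)


@dataclass(frozen=True)
class ArtificialTissue:
    name: str
    target_rho_zeff: float
    composition: ElementalComposition
    zeff: float
    rho: float
    anchors: tuple[str, str]
    adjustment_iterations: int
    interpolated_zeff: float = float("nan")  # step-i target, for diagnostics
    hu_interval: tuple[float, float] | None = None  # half-open [lo, hi)

    def as_material(self) -> Material:
        return Material(
            name=self.name, rho=self.rho, composition=self.composition, zeff=self.zeff
        )


@dataclass(frozen=True)
class TissueDatabase:
    tissues: tuple[ArtificialTissue, ...]
    curve: CalibrationCurve
    provenance: dict

    def __len__(self) -> int:
        return len(self.tissues)

    def __iter__(self):
        return iter(self.tissues)

    def boundaries(self) -> np.ndarray:
        """Interior HU boundaries plus floor/ceiling, length len+1."""
        lo = [t.hu_interval[0] for t in self.tissues]
        return np.array(lo + [self.tissues[-1].hu_interval[1]])


def _anchor_pair(
    table: Sequence[TissueTableEntry], target: float, extrapolate: bool
) -> tuple[TissueTableEntry, TissueTableEntry]:
    if any(
        b.grid_rho_zeff < a.grid_rho_zeff for a, b in zip(table, table[1:])
    ):
        raise InvalidInputError("reference table must be sorted by rho*Z_eff")
    # the ICRU table contains ties (several tissues share a printed product);
    # keep the first entry at each coordinate so spans have nonzero width
    seen: dict[float, TissueTableEntry] = {}
    for e in table:
        seen.setdefault(e.grid_rho_zeff, e)
    table = list(seen.values())
    coords = [e.grid_rho_zeff for e in table]
    if target < coords[0] or target > coords[-1]:
        if not extrapolate:
            raise RangeError(
                f"target rho*Z_eff {target} outside table range "
                f"[{coords[0]}, {coords[-1]}]"
            )
        return (table[0], table[1]) if target < coords[0] else (table[-2], table[-1])
    idx = int(np.searchsorted(coords, target, side="right"))
    idx = min(max(idx, 1), len(table) - 1)
    return table[idx - 1], table[idx]


def interpolate_tissue(
    target: float,
    icru_table: Sequence[TissueTableEntry],
    zeff_def: ZeffDefinition,
    name: str | None = None,
    extrapolate: bool = False,
) -> ArtificialTissue:
    """Generate one dose-equivalent tissue at a target rho*Z_eff.

    Follows steps i-vi documented in the module docstring.  ``extrapolate``
    permits targets slightly outside the reference span using the two
    extreme anchors (needed for the default grid's lower end, 2.0, just
    below inflated lung at 2.05).
    """
    below, above = _anchor_pair(icru_table, target, extrapolate)
    x0, x1 = below.grid_rho_zeff, above.grid_rho_zeff
    t = (target - x0) / (x1 - x0)
    target_zeff = below.printed_zeff + t * (above.printed_zeff - below.printed_zeff)

    symbols = sorted(
        set(below.material.composition.fractions)
        | set(above.material.composition.fractions),
        key=lambda s: ELEMENTS[s].Z,
    )
    w = {
        s: (1 - t) * below.material.composition[s] + t * above.material.composition[s]
        for s in symbols
    }
    if any(v < 0 for v in w.values()):
        raise GenerationError(
            f"target {target}: extrapolated mass fractions became negative"
        )

    pair = ("C", "O") if target < SOFT_BONE_BOUNDARY else ("P", "Ca")
    low_z, high_z = pair

    def zeff_of(fracs: dict[str, float]) -> float:
        return compute_zeff(
            ElementalComposition({k: v for k, v in fracs.items() if v > 0}), zeff_def
        )

    iterations = 0
    z = zeff_of(w)
    while abs(z - target_zeff) / target_zeff > ZEFF_TOLERANCE:
        if iterations >= MAX_ADJUST_ITERATIONS:
            raise ConvergenceError(
                f"target {target}: Z_eff adjustment did not converge within "
                f"{MAX_ADJUST_ITERATIONS} iterations (Z_eff {z:.3f} vs "
                f"target {target_zeff:.3f})"
            )
        # raise the higher-Z member when Z_eff is too low, and vice versa
        recipient, donor = (high_z, low_z) if z < target_zeff else (low_z, high_z)
        if recipient not in w:
            raise GenerationError(
                f"target {target}: adjustment element {recipient!r} absent from "
                f"anchors {below.name!r}/{above.name!r}; refusing to inject it"
            )
        if w.get(donor, 0.0) >= ADJUST_STEP:
            w[donor] -= ADJUST_STEP          # transfer: pair mass conserved
            w[recipient] = w.get(recipient, 0.0) + ADJUST_STEP
        else:
            # donor exhausted: move the recipient alone, hydrogen compensates
            if w.get("H", 0.0) < ADJUST_STEP and z < target_zeff:
                raise GenerationError(
                    f"target {target}: hydrogen exhausted during adjustment"
                )
            w[recipient] = w.get(recipient, 0.0) + ADJUST_STEP
            w["H"] = w.get("H", 0.0) - ADJUST_STEP
        iterations += 1
        z = zeff_of(w)

    # step v: restore the exact unit sum through hydrogen
    residual = 1.0 - sum(w.values())
    w["H"] = w.get("H", 0.0) + residual
    if w["H"] < 0:
        raise GenerationError(
            f"target {target}: hydrogen mass fraction driven below zero "
            f"({w['H']:.4f}) during renormalization"
        )
    composition = ElementalComposition({k: v for k, v in w.items() if v > 0})
    z = compute_zeff(composition, zeff_def)
    rho = target / z
    return ArtificialTissue(
        name=name or f"DET_{target:05.2f}",
        target_rho_zeff=float(target),
        composition=composition,
        zeff=z,
        rho=rho,
        anchors=(below.name, above.name),
        adjustment_iterations=iterations,
        interpolated_zeff=target_zeff,
    )


def assign_hu_intervals(
    tissues: Sequence[ArtificialTissue], curve: CalibrationCurve
) -> list[ArtificialTissue]:
    """Attach contiguous half-open HU intervals, boundaries at midpoints.

    The first interval is floored at -1000 HU (anything below is left to the
    air rule in segmentation) and the last is capped at the int16 ceiling.
    """
    if any(
        b.target_rho_zeff <= a.target_rho_zeff
        for a, b in zip(tissues, tissues[1:])
    ):
        raise InvalidInputError("tissues must be strictly sorted by target rho*Z_eff")
    centers = np.array([predict_hu(curve, t.target_rho_zeff) for t in tissues])
    if np.any(np.diff(centers) <= 0):
        raise AssignmentError(
            "predicted HU sequence is not strictly increasing; "
            "calibration curve is unusable for interval assignment"
        )
    bounds = np.empty(len(tissues) + 1)
    bounds[0] = HU_FLOOR
    bounds[-1] = HU_CEILING
    bounds[1:-1] = 0.5 * (centers[:-1] + centers[1:])
    return [
        replace(t, hu_interval=(float(lo), float(hi)))
        for t, lo, hi in zip(tissues, bounds[:-1], bounds[1:])
    ]


def build_database(
    grid: TissueGrid = DEFAULT_GRID,
    icru_table: Sequence[TissueTableEntry] | None = None,
    zeff_def: ZeffDefinition | None = None,
    curve: CalibrationCurve | None = None,
) -> TissueDatabase:
    """Generate the full artificial-tissue database on a rho*Z_eff lattice.

    Defaults: the 125-value lattice [2.0, 26.8] step 0.2, the packaged ICRU
    table, the calibrated Z_eff convention, and — if no measured curve is
    supplied — the package's reference scanner-response curve (synthetic
    module), which is monotonic over the full lattice.
    """
    from .icru import FIXTURE_VERSION, ICRU_TISSUES, default_zeff_definition

    if icru_table is None:
        icru_table = ICRU_TISSUES
    if zeff_def is None:
        zeff_def = default_zeff_definition()
    if curve is None:
        from .synthetic import make_default_curve

        curve = make_default_curve()
    if not curve.monotonic:
        raise InvalidInputError("calibration curve must be monotonic to build a database")
    tissues = []
    for target in grid.values():
        try:
            tissues.append(
                interpolate_tissue(
                    float(target), icru_table, zeff_def, extrapolate=True
                )
            )
        except GenerationError:
            raise
        except RangeError as exc:
            raise RangeError(f"grid value {target}: {exc}") from exc
    tissues = assign_hu_intervals(tissues, curve)
    provenance = {
        "grid": {"start": grid.start, "stop": grid.stop, "step": grid.step},
        "fixture": FIXTURE_VERSION,
        "zeff_definition": {
            "exponent": zeff_def.exponent,
            "weighting": zeff_def.weighting,
        },
    }
    return TissueDatabase(tissues=tuple(tissues), curve=curve, provenance=provenance)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def database_to_json(db: TissueDatabase, path: str | Path | None = None) -> str:
    payload = {
        "provenance": db.provenance,
        "curve": json.loads(curve_to_json(db.curve)),
        "tissues": [
            {
                "name": t.name,
                "target_rho_zeff": t.target_rho_zeff,
                "rho": t.rho,
                "zeff": t.zeff,
                "anchors": list(t.anchors),
                "adjustment_iterations": t.adjustment_iterations,
                "interpolated_zeff": t.interpolated_zeff,
                "hu_interval": list(t.hu_interval) if t.hu_interval else None,
                "composition": {
                    s: t.composition[s] for s in t.composition.elements()
                },
            }
            for t in db.tissues
        ],
    }
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n", encoding="utf-8")
    return text


def database_from_json(source: str | Path) -> TissueDatabase:
    p = Path(source)
    text = p.read_text(encoding="utf-8") if p.exists() else str(source)
    d = json.loads(text)
    tissues = tuple(
        ArtificialTissue(
            name=rec["name"],
            target_rho_zeff=rec["target_rho_zeff"],
            composition=ElementalComposition(rec["composition"]),
            zeff=rec["zeff"],
            rho=rec["rho"],
            anchors=tuple(rec["anchors"]),
            adjustment_iterations=rec["adjustment_iterations"],
            interpolated_zeff=rec.get("interpolated_zeff", float("nan")),
            hu_interval=tuple(rec["hu_interval"]) if rec["hu_interval"] else None,
        )
        for rec in d["tissues"]
    )
    curve = CalibrationCurve(
        coeffs=tuple(d["curve"]["coeffs"]),
        domain=tuple(d["curve"]["domain"]),
        r_squared=d["curve"]["r_squared"],
        monotonic=d["curve"]["monotonic"],
        warnings=tuple(d["curve"].get("warnings", ())),
    )
    return TissueDatabase(tissues=tissues, curve=curve, provenance=d["provenance"])


def database_to_csv(db: TissueDatabase, path: str | Path) -> None:
    symbols = sorted(
        {s for t in db.tissues for s in t.composition.fractions},
        key=lambda s: ELEMENTS[s].Z,
    )
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["name", "target_rho_zeff", "rho_g_cm3", "zeff", "hu_lo", "hu_hi", *symbols]
        )
        for t in db.tissues:
            lo, hi = t.hu_interval if t.hu_interval else ("", "")
            writer.writerow(
                [
                    t.name,
                    f"{t.target_rho_zeff:.6g}",
                    f"{t.rho:.6f}",
                    f"{t.zeff:.6f}",
                    f"{lo:.6f}" if lo != "" else "",
                    f"{hi:.6f}" if hi != "" else "",
                    *[f"{t.composition[s]:.6f}" for s in symbols],
                ]
            )
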