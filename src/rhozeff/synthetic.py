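"""Digital phantoms and simulated CBCT volumes.

Every downstream operation (calibration, database build, segmentation,
gamma comparison) can be exercised without scanner data by rasterizing a
geometric phantom with known materials and pushing it through the forward
model: HU = calibration-curve(rho*Z_eff of the voxel's material) plus
additive Gaussian noise.  Acquired 40 kVp cone-beam images carry HU noise
up to ~30 HU, so sigma is configurable in [0, 30]; the default reference
curve emulates a 40 kVp scanner response (water at 0 HU, inflated lung
around -400 HU, cortical bone around +2000 HU, mildly super-linear in
rho*Z_eff as the photoelectric channel strengthens with Z).

What this generator does NOT emulate: beam hardening, scatter gradients,
partial-volume mixing at region edges, or any projection/reconstruction
physics.  Segmentation accuracy measured on these phantoms therefore
reflects interval-lookup behaviour under additive noise only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import yaml

from .errors import InvalidInputError
from .hu_calibration import CalibrationCurve, predict_hu
from .icru import icru_tissue
from .materials import Material
from .segmentation import ImageVolume, LabelVolume

__all__ = [
    "AIR_HU",
    "PhantomSpec",
    "Region",
    "NoiseModel",
    "make_default_curve",
    "rasterize_phantom",
    "simulate_hu",
    "make_default_phantoms",
    "phantom_from_yaml",
    "phantom_to_yaml",
]

#: Nominal HU of air before noise.
AIR_HU = -1000.0


def make_default_curve() -> CalibrationCurve:
    """Reference 40 kVp scanner-response curve (monotone cubic, water -> 0 HU).

    Coefficients are fixed package constants chosen so that water
    (rho*Z_eff = 7.73) maps to exactly 0 HU, inflated lung (2.05) to about
    -400 HU and cortical bone (26.84) to about +2000 HU, with positive
    curvature mimicking the growing photoelectric contribution.
    """
    c1, c2, c3 = 60.0, 1.0, 0.012
    xw = 7.73
    c0 = -(c1 * xw + c2 * xw**2 + c3 * xw**3)
    return CalibrationCurve(coeffs=(c0, c1, c2, c3), domain=(2.0, 27.0))


GeometryKind = Literal["cylinder", "ellipsoid", "box"]


@dataclass(frozen=True)
class Region:
    """A geometric primitive filled with one material.

    Parameters are in mm, in world coordinates (origin + index * spacing):
    cylinder: center=(x, y), radius, z range [z0, z1); axis along z.
    ellipsoid: center=(x, y, z), semi_axes=(a, b, c).
    box: corner low=(x, y, z), size=(sx, sy, sz), half-open.
    """

    kind: GeometryKind
    params: dict
    material: str


@dataclass(frozen=True)
class PhantomSpec:
    """Grid dimensions + spacing and an ordered region list.

    Later regions overwrite earlier ones where they overlap; voxels outside
    every region get the background material ("air" for none).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (0.2, 0.2, 0.2)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    regions: tuple[Region, ...] = ()
    background: str = "air"

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.shape):
            raise InvalidInputError(f"phantom shape must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise InvalidInputError(f"spacing must be positive, got {self.spacing}")


@dataclass(frozen=True)
class NoiseModel:
    """Additive per-voxel Gaussian HU noise with an explicit seed."""

    sigma: float = 0.0
    seed: int = 0
    distribution: str = "gaussian"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise InvalidInputError(f"noise sigma must be >= 0, got {self.sigma}")
        if self.distribution != "gaussian":
            raise InvalidInputError("only gaussian noise is supported")


def _voxel_centers(spec: PhantomSpec):
    axes = [
        spec.origin[d] + spec.spacing[d] * (np.arange(spec.shape[d]) + 0.5)
        for d in range(3)
    ]
    return np.meshgrid(*axes, indexing="ij")


def rasterize_phantom(spec: PhantomSpec) -> LabelVolume:
    """Voxel-center containment rasterization (no partial-volume mixing).

    Returns a ground-truth label volume: 0 = background ("air"), or a
    1-based region label; the legend maps labels to material names.  If the
    background is a material (not "air") it receives the label after the
    last region.
    """
    X, Y, Z = _voxel_centers(spec)
    labels = np.zeros(spec.shape, dtype=np.int16)
    legend: dict[int, str] = {}
    for i, region in enumerate(spec.regions, start=1):
        p = region.params
        if region.kind == "cylinder":
            cx, cy = p["center"]
            inside = (X - cx) ** 2 + (Y - cy) ** 2 <= p["radius"] ** 2
            z0, z1 = p.get("z_range", (-np.inf, np.inf))
            inside &= (Z >= z0) & (Z < z1)
        elif region.kind == "ellipsoid":
            cx, cy, cz = p["center"]
            a, b, c = p["semi_axes"]
            inside = (
                ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 + ((Z - cz) / c) ** 2 <= 1.0
            )
        elif region.kind == "box":
            lx, ly, lz = p["low"]
            sx, sy, sz = p["size"]
            inside = (
                (X >= lx) & (X < lx + sx)
                & (Y >= ly) & (Y < ly + sy)
                & (Z >= lz) & (Z < lz + sz)
            )
        else:
            raise InvalidInputError(f"unknown geometry kind {region.kind!r}")
        labels[inside] = i
        legend[i] = region.material
    if spec.background != "air":
        bg_label = len(spec.regions) + 1
        labels[labels == 0] = bg_label
        legend[bg_label] = spec.background
    return LabelVolume(
        labels=labels, legend=legend, spacing=spec.spacing, origin=spec.origin
    )


def simulate_hu(
    truth: LabelVolume,
    materials: Mapping[str, Material],
    curve: CalibrationCurve,
    noise: NoiseModel = NoiseModel(),
) -> ImageVolume:
    """Forward-model a CBCT volume: HU = curve(rho*Z_eff) + N(0, sigma).

    Air voxels (label 0) are set to -1000 HU before noise.
    """
    unknown = {
        name
        for label, name in truth.legend.items()
        if label != 0 and name not in materials
    }
    if unknown:
        raise InvalidInputError(f"no material given for: {sorted(unknown)}")
    hu_by_label = np.full(int(truth.labels.max()) + 1, AIR_HU)
    for label, name in truth.legend.items():
        hu_by_label[label] = predict_hu(curve, materials[name].rho_zeff)
    hu = hu_by_label[truth.labels].astype(np.float64)
    if noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        hu = hu + rng.normal(0.0, noise.sigma, size=hu.shape)
    return ImageVolume(values=hu, spacing=truth.spacing, origin=truth.origin)


#: The eight reference tissues filling the default cylinder battery,
#: spanning soft tissue to cortical bone in rho*Z_eff.
DEFAULT_CYLINDER_MATERIALS = (
    "Adipose", "Water", "Muscle", "Thyroid", "Spongiosa", "Femur",
    "Cranium", "Cortical bone",
)


def default_materials() -> dict[str, Material]:
    """Name -> Material map for the default phantoms (from the ICRU table)."""
    names = set(DEFAULT_CYLINDER_MATERIALS) | {
        "Lung inflated", "Average soft tissue adult male",
    }
    return {n: icru_tissue(n).material for n in names}


def make_default_phantoms() -> tuple[PhantomSpec, PhantomSpec]:
    """Deterministic (cylinder-battery, mouse-like) phantom pair.

    The cylinder battery holds eight rods of distinct reference materials in
    air, soft tissue through cortical bone.  The mouse-like phantom is an
    ellipsoidal soft-tissue body containing two inflated-lung pockets and
    two bone rods, in air.
    """
    nx = ny = 48
    nz = 8
    spacing = (0.2, 0.2, 0.2)
    extent = nx * spacing[0]  # 9.6 mm
    rods = []
    # 8 rods on a 4x2 layout
    for i, mat in enumerate(DEFAULT_CYLINDER_MATERIALS):
        cx = (0.15 + 0.235 * (i % 4)) * extent
        cy = (0.3 + 0.4 * (i // 4)) * extent
        rods.append(
            Region("cylinder", {"center": (cx, cy), "radius": 0.08 * extent}, mat)
        )
    cylinders = PhantomSpec(shape=(nx, ny, nz), spacing=spacing, regions=tuple(rods))

    body = Region(
        "ellipsoid",
        {"center": (extent / 2, extent / 2, nz * spacing[2] / 2),
         "semi_axes": (0.45 * extent, 0.35 * extent, nz * spacing[2])},
        "Average soft tissue adult male",
    )
    lungs = [
        Region(
            "ellipsoid",
            {"center": ((0.35 + 0.3 * k) * extent, 0.5 * extent, nz * spacing[2] / 2),
             "semi_axes": (0.09 * extent, 0.12 * extent, nz * spacing[2])},
            "Lung inflated",
        )
        for k in range(2)
    ]
    bones = [
        Region(
            "cylinder",
            {"center": ((0.28 + 0.44 * k) * extent, 0.22 * extent),
             "radius": 0.05 * extent},
            "Femur",
        )
        for k in range(2)
    ]
    mouse = PhantomSpec(
        shape=(nx, ny, nz), spacing=spacing,
        regions=(body, *lungs, *bones),
    )
    return cylinders, mouse


# ---------------------------------------------------------------------------
# YAML phantom specs
# ---------------------------------------------------------------------------

def phantom_to_yaml(spec: PhantomSpec, path: str | Path) -> None:
    payload = {
        "shape": list(spec.shape),
        "spacing": list(spec.spacing),
        "origin": list(spec.origin),
        "background": spec.background,
        "regions": [
            {"kind": r.kind, "material": r.material,
             "params": {k: (list(v) if isinstance(v, (tuple, list)) else v)
                        for k, v in r.params.items()}}
            for r in spec.regions
        ],
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True), encoding="utf-8")


def phantom_from_yaml(path: str | Path) -> PhantomSpec:
    d = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    regions = tuple(
        Region(
            kind=r["kind"],
            params={k: (tuple(v) if isinstance(v, list) else v)
                    for k, v in r["params"].items()},
            material=r["material"],
        )
        for r in d.get("regions", ())
    )
    return PhantomSpec(
        shape=tuple(d["shape"]),
        spacing=tuple(d.get("spacing", (0.2, 0.2, 0.2))),
        origin=tuple(d.get("origin", (0.0, 0.0, 0.0))),
        regions=regions,
        background=d.get("background", "air"),
    )
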