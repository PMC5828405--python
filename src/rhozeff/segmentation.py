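"""Voxel-wise tissue assignment on CBCT volumes and Monte-Carlo export.

Once the tissue database carries contiguous half-open HU intervals,
segmentation is a pure per-voxel interval lookup: voxels below the air
threshold become air (label 0), every other voxel gets the unique tissue
whose interval contains its HU.  The result is a label volume plus a
legend, exportable alongside GATE/Geant4-style material and HU-range
files so a Monte-Carlo engine can ingest the segmented animal directly.

Volumes are axis-aligned scalar grids indexed (x, y, z), world position =
origin + index * spacing; orientation matrices are not supported (CBCT
exports in this workflow are axis-aligned).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import SimpleITK as sitk

from .errors import ExportError, InvalidInputError, VolumeIOError
from .periodic import ELEMENT_NAMES, ELEMENTS
from .tissue_db import TissueDatabase

__all__ = [
    "DEFAULT_AIR_THRESHOLD",
    "ImageVolume",
    "LabelVolume",
    "read_volume",
    "write_volume",
    "segment_volume",
    "export_mc_materials",
    "read_mc_materials",
]

#: Default HU below which a voxel is air: below any HU the reference curve
#: assigns to the lightest tissue (mice contain air cavities; the scanner
#: background is air).
DEFAULT_AIR_THRESHOLD = -475.0


@dataclass
class ImageVolume:
    """3D HU grid with spacing and origin in mm, indexed (x, y, z)."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise InvalidInputError(
                f"volume must be 3D with all dimensions >= 1, got {self.values.shape}"
            )
        if any(s <= 0 for s in self.spacing):
            raise InvalidInputError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class LabelVolume:
    """Integer tissue labels (same shape as the source; 0 is air) + legend."""

    labels: np.ndarray
    legend: dict[int, str] = field(default_factory=dict)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.legend)
        if missing:
            raise InvalidInputError(f"labels without legend entry: {sorted(missing)}")


_FORMATS = {".mhd": "MetaImage", ".nii": "NIfTI", ".gz": "NIfTI"}


def _check_format(path: Path) -> None:
    suffix = path.suffix.lower()
    if suffix == ".gz" and not path.name.lower().endswith(".nii.gz"):
        raise VolumeIOError(f"unsupported volume format: {path.name}")
    if suffix not in _FORMATS:
        raise VolumeIOError(
            f"unsupported volume format {suffix!r} (use .mhd, .nii or .nii.gz)"
        )


def read_volume(path: str | Path) -> ImageVolume:
    """Read a MetaImage (.mhd/.raw) or NIfTI volume.

    Integer voxel data are preserved bit-exactly; spacing and origin come
    from the header.
    """
    path = Path(path)
    _check_format(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise VolumeIOError(f"failed to read {path}: {exc}") from exc
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    if arr.ndim != 3:
        raise VolumeIOError(f"{path}: expected a 3D volume, got {arr.ndim}D")
    return ImageVolume(
        values=arr.transpose(2, 1, 0),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
    )


def write_volume(volume: ImageVolume | LabelVolume, path: str | Path) -> None:
    """Write a volume as MetaImage or NIfTI (int data as 16-bit, float as 32)."""
    path = Path(path)
    _check_format(path)
    arr = volume.values if isinstance(volume, ImageVolume) else volume.labels
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.int16)
    else:
        arr = arr.astype(np.float32)
    img = sitk.GetImageFromArray(arr.transpose(2, 1, 0))
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.origin))
    sitk.WriteImage(img, str(path))


def segment_volume(
    volume: ImageVolume,
    db: TissueDatabase,
    air_threshold: float = DEFAULT_AIR_THRESHOLD,
    override_mask: np.ndarray | None = None,
    override_label: int | None = None,
) -> LabelVolume:
    """Assign a database tissue to every voxel by HU interval lookup.

    Labels are 1-based indices into ``db.tissues``; label 0 is air
    (HU < ``air_threshold``).  HU outside the tiled range clamps to the
    first/last tissue.  ``override_mask``/``override_label`` force a label
    in a region (e.g. dense cylinders whose centre suffers beam hardening,
    relabelled from their peripheral HU).
    """
    if volume.values.size == 0:
        raise InvalidInputError("empty volume")
    from .hu_calibration import predict_hu

    # the first interval is floored at -1000 HU; the physically meaningful
    # start of the first tissue is its predicted HU centre
    first_center = predict_hu(db.curve, db.tissues[0].target_rho_zeff)
    if air_threshold > first_center:
        raise InvalidInputError(
            f"air_threshold {air_threshold} must not exceed the first tissue's "
            f"predicted HU {first_center:.1f}"
        )
    hu = volume.values
    # interior boundaries only: searchsorted tiles (-inf, b0], (b0, b1] ... —
    # with side='right' each half-open [lo, hi) maps to one label
    interior = db.boundaries()[1:-1]
    labels = np.searchsorted(interior, hu, side="right").astype(np.int16) + 1
    labels[hu < air_threshold] = 0
    if override_mask is not None:
        if override_label is None:
            raise InvalidInputError("override_mask given without override_label")
        labels[np.asarray(override_mask, dtype=bool)] = override_label
    legend = {i + 1: t.name for i, t in enumerate(db.tissues)}
    return LabelVolume(
        labels=labels, legend=legend, spacing=volume.spacing, origin=volume.origin
    )


# ---------------------------------------------------------------------------
# Monte-Carlo (GATE-style) export
# ---------------------------------------------------------------------------

def export_mc_materials(
    db: TissueDatabase,
    materials_path: str | Path,
    ranges_path: str | Path,
    legend: Mapping[int, str] | None = None,
) -> None:
    """Write a GATE-compatible materials database and HU-range file.

    The materials file holds one record per tissue (name, density, element
    count, per-element mass fractions, 6 decimals); the range file one line
    per tissue, ``HU_lo HU_hi name``, contiguous and matching the database
    intervals.  ``legend`` may rename tissues (labels from a segmentation).
    """
    names = [t.name for t in db.tissues]
    if legend is not None:
        renames = dict(legend)
        names = [renames.get(i + 1, t.name) for i, t in enumerate(db.tissues)]
    if len(set(names)) != len(names):
        raise ExportError("duplicate tissue names in export")
    lines = ["[Materials]"]
    for t, name in zip(db.tissues, names):
        symbols = t.composition.elements()
        lines.append(f"{name}: d={t.rho:.6f} g/cm3 ; n={len(symbols)}")
        for s in symbols:
            lines.append(f"  +el: name={ELEMENT_NAMES[s]} ; f={t.composition[s]:.6f}")
    Path(materials_path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    range_lines = []
    for t, name in zip(db.tissues, names):
        lo, hi = t.hu_interval
        range_lines.append(f"{lo:.3f} {hi:.3f} {name}")
    Path(ranges_path).write_text("\n".join(range_lines) + "\n", encoding="utf-8")


_NAME_TO_SYMBOL = {v: k for k, v in ELEMENT_NAMES.items()}


def read_mc_materials(materials_path: str | Path) -> list[dict]:
    """Parse back an exported materials file (round-trip checks, reuse)."""
    records: list[dict] = []
    for line in Path(materials_path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("["):
            continue
        if line.startswith("+el:"):
            body = line[len("+el:"):].strip()
            parts = dict(p.split("=") for p in body.replace(" ", "").split(";"))
            records[-1]["fractions"][_NAME_TO_SYMBOL[parts["name"]]] = float(parts["f"])
        else:
            name, rest = line.split(":", 1)
            d_part, n_part = rest.split(";")
            rho = float(d_part.strip().split("=")[1].split()[0])
            records.append({"name": name.strip(), "rho": rho, "fractions": {}})
    return records


def write_legend_json(label_volume: LabelVolume, path: str | Path) -> None:
    payload = {"air_label": 0, "legend": {str(k): v for k, v in sorted(label_volume.legend.items())}}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
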