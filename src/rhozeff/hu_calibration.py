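"""Cubic calibration between rho*Z_eff and CBCT number.

Scanning inserts of known composition at the imaging energy (40 kVp here)
yields one (rho*Z_eff, HU) point per insert.  A third-degree polynomial

    HU(x) = c0 + c1 x + c2 x^2 + c3 x^3,   x = rho * Z_eff

fitted by ordinary least squares captures the relationship; on a well-behaved
scanner it is strictly monotonic over the calibrated range, which is what
makes the inverse map (HU -> rho*Z_eff) — and hence voxel-wise material
assignment — well defined.  Monotonicity is checked, not enforced: a
non-monotone fit is a calibration problem the user must see, not hide.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import FitError, InvalidInputError, InversionError

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "ExtrapolationWarning",
    "InversionResult",
    "fit_curve",
    "predict_hu",
    "invert_hu",
    "read_points_csv",
    "curve_to_json",
    "curve_from_json",
]


@dataclass(frozen=True)
class CalibrationPoint:
    rho_zeff: float  # g/cm^3
    hu: float

    def __post_init__(self) -> None:
        if self.rho_zeff <= 0:
            raise InvalidInputError(f"rho_zeff must be > 0, got {self.rho_zeff}")


@dataclass(frozen=True)
class CalibrationCurve:
    """HU = c0 + c1 x + c2 x^2 + c3 x^3 over domain [x_min, x_max]."""

    coeffs: tuple[float, float, float, float]
    domain: tuple[float, float]
    r_squared: float = 1.0
    monotonic: bool = True
    warnings: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.coeffs) != 4:
            raise InvalidInputError("curve needs exactly 4 coefficients c0..c3")
        if not self.domain[0] < self.domain[1]:
            raise InvalidInputError(f"degenerate domain {self.domain}")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise InvalidInputError(f"r_squared out of [0, 1]: {self.r_squared}")

    def __call__(self, x):
        return predict_hu(self, x)

    def contains(self, x) -> np.ndarray | bool:
        lo, hi = self.domain
        return (np.asarray(x) >= lo) & (np.asarray(x) <= hi)


class ExtrapolationWarning(UserWarning):
    """Prediction requested outside the calibrated rho*Z_eff domain."""


class InversionResult(NamedTuple):
    rho_zeff: float
    clamped: bool


def _derivative_min(coeffs, lo, hi) -> float:
    """Minimum of dHU/dx over [lo, hi] (derivative is a quadratic)."""
    c0, c1, c2, c3 = coeffs
    candidates = [lo, hi]
    # stationary point of the derivative: 6 c3 x + 2 c2 = 0
    if c3 != 0:
        x_star = -c2 / (3.0 * c3)
        if lo < x_star < hi:
            candidates.append(x_star)
    d = lambda x: c1 + 2 * c2 * x + 3 * c3 * x * x
    return min(d(x) for x in candidates)


def fit_curve(points: Sequence[CalibrationPoint]) -> CalibrationCurve:
    """Ordinary least-squares cubic of HU on rho*Z_eff.

    Requires at least 5 distinct points (4 coefficients plus one degree of
    freedom for the diagnostics to mean anything).  r_squared is the squared
    Pearson correlation between fitted and observed HU.
    """
    if len(points) < 5:
        raise FitError(f"need at least 5 calibration points, got {len(points)}")
    x = np.array([p.rho_zeff for p in points], dtype=float)
    y = np.array([p.hu for p in points], dtype=float)
    if np.unique(x).size < 5:
        raise FitError("need at least 5 distinct rho_zeff values")
    # fit in a scaled domain for conditioning, then convert back to c0..c3
    series = np.polynomial.Polynomial.fit(x, y, deg=3)
    coeffs = tuple(float(c) for c in series.convert().coef)
    coeffs = coeffs + (0.0,) * (4 - len(coeffs))
    fitted = series(x)
    if np.allclose(y, y[0]):
        r2 = 1.0 if np.allclose(fitted, y) else 0.0
    else:
        r = np.corrcoef(fitted, y)[0, 1]
        r2 = float(min(r * r, 1.0))
    lo, hi = float(x.min()), float(x.max())
    mono = _derivative_min(coeffs, lo, hi) > 0
    warnings = () if mono else (
        "fitted cubic is not monotonically increasing over the calibration "
        "domain; inversion (and hence segmentation) is disabled — recalibrate",
    )
    return CalibrationCurve(
        coeffs=coeffs, domain=(lo, hi), r_squared=r2, monotonic=mono,
        warnings=warnings,
    )


def predict_hu(curve: CalibrationCurve, rho_zeff) -> float | np.ndarray:
    """Evaluate the calibration polynomial.

    Values outside the calibrated domain are extrapolated, with an
    ``ExtrapolationWarning`` so the caller knows the prediction rests on the
    polynomial's tails rather than on measured inserts.
    """
    x = np.asarray(rho_zeff, dtype=float)
    if np.any(~curve.contains(x)):
        import warnings as _warnings

        _warnings.warn(
            "rho_zeff outside the calibration domain "
            f"[{curve.domain[0]:g}, {curve.domain[1]:g}]; extrapolating",
            ExtrapolationWarning,
            stacklevel=2,
        )
    c0, c1, c2, c3 = curve.coeffs
    out = c0 + x * (c1 + x * (c2 + x * c3))
    if out.ndim == 0:
        return float(out)
    return out


def invert_hu(curve: CalibrationCurve, hu: float, tol: float = 1e-6) -> InversionResult:
    """Map an HU value back to rho*Z_eff on a monotonic curve.

    Root-bracketing to |delta HU| < ``tol`` inside the domain; HU outside the
    calibrated HU range clamps to the nearest domain endpoint with the
    ``clamped`` flag set (scanner artifacts produce out-of-range HU that must
    still map to a physical material).
    """
    if not curve.monotonic:
        raise InversionError(
            "calibration curve is not monotonic over its domain; "
            "recalibrate before inverting"
        )
    lo, hi = curve.domain
    hu_lo, hu_hi = predict_hu(curve, lo), predict_hu(curve, hi)
    if hu <= hu_lo:
        return InversionResult(lo, clamped=hu < hu_lo)
    if hu >= hu_hi:
        return InversionResult(hi, clamped=hu > hu_hi)
    x = brentq(lambda t: predict_hu(curve, t) - hu, lo, hi, xtol=1e-12, rtol=1e-15)
    assert abs(predict_hu(curve, x) - hu) < tol
    return InversionResult(float(x), clamped=False)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def read_points_csv(path: str | Path) -> list[CalibrationPoint]:
    """Calibration points CSV with columns rho_zeff, hu."""
    import csv

    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"rho_zeff", "hu"} <= set(reader.fieldnames):
            raise InvalidInputError(f"{path}: need columns rho_zeff, hu")
        return [
            CalibrationPoint(float(row["rho_zeff"]), float(row["hu"]))
            for row in reader
        ]


def curve_to_json(curve: CalibrationCurve, path: str | Path | None = None) -> str:
    payload = {
        "coeffs": list(curve.coeffs),
        "domain": list(curve.domain),
        "r_squared": curve.r_squared,
        "monotonic": curve.monotonic,
        "warnings": list(curve.warnings),
    }
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n", encoding="utf-8")
    return text


def curve_from_json(source: str | Path) -> CalibrationCurve:
    p = Path(source)
    text = p.read_text(encoding="utf-8") if p.exists() else str(source)
    d = json.loads(text)
    return CalibrationCurve(
        coeffs=tuple(d["coeffs"]),
        domain=tuple(d["domain"]),
        r_squared=d.get("r_squared", 1.0),
        monotonic=d.get("monotonic", True),
        warnings=tuple(d.get("warnings", ())),
    )
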