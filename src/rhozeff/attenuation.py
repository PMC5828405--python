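"""Parameterized photon attenuation and the stoichiometric HU calibration.

The linear attenuation coefficient of a mixture is written as a three-term
parameterization (Jackson-Hawkes form):

    mu = rho * sum_i (w_i / A_i) * (K_kn * Z_i + K_ph * Z_i**4.62 + K_sca * Z_i**2.86)

with one term per interaction channel: Klein-Nishina (incoherent) scattering,
photoelectric absorption, and coherent/incoherent scattering corrections.
Avogadro's number and any overall unit scale cancel in the CT-number ratio

    CT = 1000 * (mu / mu_water - 1)

so the coefficients carry arbitrary units and only their ratios matter.
The stoichiometric calibration fits the coefficient ratios to measured HU of
known materials; at kV cone-beam geometries the scatter-heavy beam makes
this fit a poor predictor (it is included here so that failure mode can be
studied on data), while the rho*Z_eff calibration in
:mod:`rhozeff.hu_calibration` is the method of choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import FitError, InvalidInputError
from .materials import Material
from .periodic import ELEMENTS

__all__ = [
    "PH_EXPONENT",
    "SCA_EXPONENT",
    "AttenuationCoefficients",
    "StoichiometricFitResult",
    "mu",
    "ct_number",
    "fit_stoichiometric",
]

#: Fixed exponents of the photoelectric and coherent-scatter terms.
PH_EXPONENT = 4.62
SCA_EXPONENT = 2.86


@dataclass(frozen=True)
class AttenuationCoefficients:
    """Channel coefficients (arbitrary consistent units; ratios matter)."""

    k_kn: float
    k_ph: float
    k_sca: float

    def __post_init__(self) -> None:
        if self.k_kn == 0 and self.k_ph == 0 and self.k_sca == 0:
            raise InvalidInputError("at least one attenuation coefficient must be nonzero")

    def as_array(self) -> np.ndarray:
        return np.array([self.k_kn, self.k_ph, self.k_sca])


@dataclass(frozen=True)
class StoichiometricFitResult:
    coefficients: AttenuationCoefficients
    residuals: np.ndarray  # predicted - measured HU, per material
    rms_hu: float
    n_iterations: int

    def predicted_hu(self, measured_hu: Sequence[float]) -> np.ndarray:
        return np.asarray(measured_hu, dtype=float) + self.residuals


def _channel_sums(material: Material) -> np.ndarray:
    """rho * sum_i (w_i/A_i) * (Z, Z**4.62, Z**2.86) — mu is linear in the
    coefficients with these three numbers as the design row."""
    s = np.zeros(3)
    for sym, w in material.composition.fractions.items():
        el = ELEMENTS[sym]
        z = float(el.Z)
        s += (w / el.A) * np.array([z, z**PH_EXPONENT, z**SCA_EXPONENT])
    return material.rho * s


def mu(material: Material, coeffs: AttenuationCoefficients) -> float:
    """Parameterized attenuation value (arbitrary units, linear in rho)."""
    return float(_channel_sums(material) @ coeffs.as_array())


def ct_number(
    material: Material,
    coeffs: AttenuationCoefficients,
    water: Material | None = None,
) -> float:
    """CT number 1000*(mu/mu_water - 1); water itself maps to exactly 0."""
    if water is None:
        from .icru import WATER as water  # late import avoids a cycle
    mu_w = mu(water, coeffs)
    if mu_w == 0:
        raise InvalidInputError("mu_water is zero; CT number undefined")
    return 1000.0 * (mu(material, coeffs) / mu_w - 1.0)


def fit_stoichiometric(
    materials: Sequence[Material],
    measured_hu: Sequence[float],
    water: Material | None = None,
    tol_hu: float = 1e-6,
    max_iter: int = 100,
) -> StoichiometricFitResult:
    """Least-squares fit of the coefficient ratios to measured HU.

    K_kn is fixed to 1 (the overall scale cancels in the CT-number ratio),
    leaving (K_ph, K_sca).  The coefficients enter mu_water as well as each
    material's mu, so the fit proceeds in two stages: a water-renormalized
    linear solve of mu_m - (HU_m/1000 + 1) * mu_water = 0 (exact on
    noise-free data), then Gauss-Newton refinement of the HU residuals
    until predictions change by less than ``tol_hu``.
    """
    if water is None:
        from .icru import WATER as water
    if len(materials) != len(measured_hu):
        raise InvalidInputError("materials and measured_hu must align")
    if len(materials) < 3:
        raise FitError(f"need at least 3 materials, got {len(materials)}")
    hu = np.asarray(measured_hu, dtype=float)
    S = np.vstack([_channel_sums(m) for m in materials])  # (n, 3)
    Sw = _channel_sums(water)
    c = hu / 1000.0 + 1.0

    # stage 1: (S_m - c_m * S_water) @ k = 0 with k_kn = 1 is linear in
    # (k_ph, k_sca); the c_m * S_water term is the water renormalization
    D = S - np.outer(c, Sw)
    A, b = D[:, 1:], -D[:, 0]
    if np.linalg.matrix_rank(A, tol=1e-10 * np.abs(A).max()) < 2:
        raise FitError("rank-deficient design: materials do not separate the "
                       "photoelectric and scatter channels")
    p, *_ = np.linalg.lstsq(A, b, rcond=None)

    def predict(p):
        k = np.array([1.0, p[0], p[1]])
        return 1000.0 * (S @ k / float(Sw @ k) - 1.0), k

    # stage 2: Gauss-Newton on r(p) = predicted_HU(p) - hu
    pred, k = predict(p)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mu_w = float(Sw @ k)
        mu_m = S @ k
        J = 1000.0 * (S[:, 1:] * mu_w - np.outer(mu_m, Sw[1:])) / mu_w**2
        delta, *_ = np.linalg.lstsq(J, hu - pred, rcond=None)
        p = p + delta
        new_pred, k = predict(p)
        done = np.max(np.abs(new_pred - pred)) < tol_hu
        pred = new_pred
        if done:
            break
    residuals = pred - hu
    return StoichiometricFitResult(
        coefficients=AttenuationCoefficients(*k),
        residuals=residuals,
        rms_hu=float(np.sqrt(np.mean(residuals**2))),
        n_iterations=n_iter,
    )
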