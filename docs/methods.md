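# Methods

## Model overview

At kilovoltage photon energies the absorbed dose in tissue depends on both
mass density ρ (Compton channel) and elemental composition (photoelectric
channel, cross-section ∝ Z³–Z⁴). The package's central object is the
scalar ρZ_eff, the product of density and effective atomic number, which
on 40 kVp cone-beam CT acquisitions stands in a monotone cubic
relationship with the CBCT number. Segmentation then proceeds in three
steps: (1) fit HU = P₃(ρZ_eff) on scanned inserts of known composition,
(2) generate artificial "dose-equivalent" tissues on a regular ρZ_eff
lattice and attach each one's half-open HU interval, (3) assign each voxel
the tissue whose interval contains its HU.

## Effective atomic number

No single Z_eff convention is universal; published conventions (Mayneord's
β=2.94 electron-fraction form, mass-fraction forms with β≈3.5) disagree by
several percent on water. The package makes the convention an explicit,
calibratable object:

    Z_eff = (Σᵢ aᵢ Zᵢ^β)^(1/β)

with aᵢ the normalized mass fractions or normalized electron fractions
wᵢZᵢ/Aᵢ. `calibrate_zeff_definition` grid-searches β ∈ [2.5, 5.0] (step
0.01) × both weightings against the published reference Z_eff values of
the ICRU 44/46 tissue table and returns the RMS-minimizing pair; on the
packaged table this lands at **β = 3.51, mass-fraction weighting**
(RMS 0.03, every soft tissue within 2% of its published value). Ties break
toward smaller β; fewer than 10 table entries flag the result as
under-determined.

### Reference tissue fixture

The packaged table holds 34 ICRU 44/46 tissues with published ρ, Z_eff and
ρZ_eff plus elemental mass fractions from the public reference
compilations. Three rows are reconstructed rather than transcribed
(marked in `icru.py`): urinary bladder (filled) and pediatric cortical
bone, which the public tables do not list element-by-element, and breast,
whose common mammary-gland transcription is irreconcilable with the
published Z_eff of 7.88 under any convention in the search grid. The
published scalar values are authoritative throughout. A few published
products differ from round(ρ·Z_eff, 2) by one unit in the last place
(the publishers used unrounded inputs); integrity tests therefore check
only the self-consistent rows.

## Attenuation model and the stoichiometric fit

The three-channel parameterization
μ = ρ Σᵢ (wᵢ/Aᵢ)(K_kn Zᵢ + K_ph Zᵢ^4.62 + K_sca Zᵢ^2.86) feeds
CT = 1000(μ/μ_water − 1); the overall coefficient scale cancels, so K_kn
is fixed at 1 and (K_ph, K_sca) are fitted to measured HU. Because the
coefficients also enter μ_water, the fit first solves the exactly
equivalent linear system μ_m − (HU_m/1000 + 1)μ_water = 0 (exact on
noise-free data), then refines with Gauss–Newton on the HU residuals to
the true least-squares optimum (a naive alternation between a linear
solve and a water renormalization oscillates and never converges; the
two-stage scheme agrees with a brute-force Levenberg–Marquardt fit to
better than 0.1 HU). The exponents 4.62 and 2.86 are fixed constants of
the parameterization, not fit parameters. No energy-spectrum, scatter or
beam-hardening physics is modelled: on CBCT-like data the fit simply
exhibits the large residuals that motivate the ρZ_eff route.

## Calibration curve

`fit_curve` is an unweighted OLS cubic of HU on ρZ_eff (≥5 distinct
points), fitted in a scaled domain for conditioning. r² is the squared
Pearson correlation between fitted and observed HU. Monotonicity is
*checked* (sign of the derivative at the domain ends and at the
derivative's stationary point), never enforced: a non-monotone fit marks
the curve and hard-blocks inversion, because voxel assignment is
meaningless without a one-to-one HU↔ρZ_eff map. Inversion uses Brent
root-bracketing to |ΔHU| < 1e-6; HU outside the calibrated range clamps
to the nearest domain endpoint with a flag (scanner artifacts must still
map to a physical tissue). Out-of-domain predictions extrapolate with an
`ExtrapolationWarning`.

The package also ships a fixed reference curve (`make_default_curve`),
coefficients (c₁, c₂, c₃) = (60, 1.0, 0.012) with c₀ chosen so water
(7.73) maps to exactly 0 HU: a monotone cubic placing inflated lung near
−400 HU and cortical bone near +2000 HU, with mild positive curvature
mimicking the growing photoelectric contribution at high Z. It drives the
synthetic forward model and serves as the default when no measured curve
is supplied.

## Dose-equivalent tissue database

Monte-Carlo studies of kV dose deposition indicate that a ρZ_eff spacing
of 0.2 g/cm³ keeps the dose difference between neighbouring tissues below
~2%; the 0.2 step is adopted here as a given parameter. The default
lattice is {2.0 + 0.2k, k = 0..124} = [2.0, 26.8] — the span "2 to 27 in
steps of 0.2" contains 126 lattice points but the database holds 125
tissues, so one endpoint is open; the lower endpoint is kept and cortical
bone (26.84) still anchors the top interpolation. Each tissue is built
from the two reference tissues bracketing its target (published ρZ_eff
values as coordinates; ties in the table collapse to the first entry):
Z_eff and mass fractions are linearly interpolated, Z_eff is recomputed
from the interpolated fractions, and while it deviates from the
interpolated target by more than 5% (relative), 0.001 of mass per step is
transferred within the regime pair — C/O below ρZ_eff = 10, Ca/P at and
above it — toward the higher-Z member when Z_eff is too low. The pair
transfer conserves the pair's mass; if the donor is exhausted the
recipient moves alone with hydrogen compensating; the final sum is
restored to exactly 1 through hydrogen (Z = 1, negligible Z_eff impact).
The density follows as ρ = target/Z_eff, so ρ·Z_eff matches the lattice
value to 1e-6 by construction. An iteration cap of 2000 turns pathological
targets into diagnosable errors, and a missing regime element in both
anchors is an error, never a silent injection. With the packaged table
the interpolated compositions already reproduce the published Z_eff, so
the adjustment loop runs zero iterations on every default-lattice tissue.

The lattice's lower end (2.0) lies slightly below the lightest reference
tissue (inflated lung, 2.05); the builder permits linear extrapolation
with the two extreme anchors there. Note that the reference table itself
is not monotone in Z_eff along ρZ_eff (water 7.73 precedes male soft
tissue 7.60), so generated Z_eff inherits those dips in the soft-tissue
range; it is monotone in the bony regime.

HU intervals are half-open [lo, hi), boundaries at the midpoints of
consecutive predicted HU centres, the first floored at −1000 HU and the
last capped at 32767 (int16 ceiling), so the intervals tile the HU axis
and assignment is a pure `searchsorted`. Ties at a boundary go to the
upper tissue.

## Segmentation

Volumes are axis-aligned (x, y, z) grids, world = origin + index·spacing;
no orientation matrices (CBCT exports in this workflow are axis-aligned).
I/O goes through SimpleITK (MetaImage MET_SHORT/MET_FLOAT and NIfTI),
preserving integer HU bit-exactly. Voxels below the air threshold
(default −475 HU, below any HU the reference curve assigns to the
lightest tissue) become air (label 0). Beam-hardening in dense objects is
not corrected; an override-mask mechanism lets the user relabel such
regions (e.g. from peripheral HU) instead. Exports follow the GATE
materials-database layout (name, density, per-element mass fractions at
6 decimals) plus a contiguous `HU_lo HU_hi name` range file.

## Gamma analysis

2D global-normalization gamma with dose-difference dd (% of the reference
maximum) and distance-to-agreement dta (mm); defaults 4% / 0.3 mm, with a
10% isodose evaluation mask and 80% isodose difference statistics. The
target is bilinearly interpolated on a fine offset lattice within a
3·dta search radius, nearest offsets first with an early exit once the
distance term alone exceeds every remaining pixel's best γ². The search
pitch defaults to dta/50: the often-quoted dta/10 is insufficient near
mm-scale penumbrae, where the dose gradient traverses the entire DD
window within a fraction of the DTA and the γ optimum falls between
dta/10 lattice sites (errors up to ~0.1 were measured on synthetic beam
fields; dta/50 keeps the granularity error below 0.02). Reference pixels
are never interpolated; planes are assumed pre-registered.

## Synthetic phantoms

`rhozeff.synthetic` rasterizes cylinder/ellipsoid/box primitives by
voxel-centre containment (later regions win; no partial-volume mixing, so
ground truth is unambiguous) and forward-models HU as
curve(ρZ_eff) + N(0, σ) with an explicit seed; air is −1000 HU before
noise. σ is configurable in [0, 30] HU — acquired 40 kVp CBCT images carry
noise up to about 30 HU, and Gaussian is the minimal model for it, a
parameter rather than a claim. The default phantoms are an 8-rod cylinder
battery (adipose through cortical bone) and a mouse-like ellipsoid body
with lung pockets and bone rods, both on a 0.2 mm grid; test phantoms are
48×48×8 voxels, small enough that the 20-seed end-to-end accuracy suite
runs in seconds while still sampling every tissue class.

What the generator does *not* emulate — and hence what passing tests do
not demonstrate about real scanner data: beam hardening, scatter
gradients, reconstruction artifacts, partial-volume mixing at interfaces,
or spatially correlated noise. The end-to-end accuracy figures (exact
recovery at σ=0; ≥95% of non-air voxels within ±1 lattice step at σ=10
across 20 seeds) characterize interval lookup under additive noise only.
Validation against measured film dosimetry and Monte-Carlo transport
requires hardware and a transport engine and is out of scope; the package
exports GATE-ready materials for exactly that purpose.

## Numerical and design choices

- Composition sums are renormalized at construction and checked to 1e-6
  (reference tables round to 3–4 decimals).
- Cubic fitting uses numpy's scaled-domain `Polynomial.fit`, recovering
  exact coefficients to ~1e-12 on noise-free data.
- The Z_eff power sums are evaluated in log space, well-conditioned up to
  iodine at β = 6.
- Database generation is fully deterministic: identical inputs give
  bit-identical JSON/CSV, which the pipeline's reproducibility contract
  (and its tests) rely on.
- `run` (CLI) validates configuration before any stage executes and
  embeds the tool version, config hash and artifact hashes in its report.

## Known limitations

- The stoichiometric module reproduces the *mechanics* of the classic
  calibration, not the physics of why it fails on cone-beam geometries.
- Z_eff is a scalar compression of composition; distinct mixtures with
  equal ρZ_eff are indistinguishable by construction.
- The artificial tissues have no anatomical meaning; they are
  dose-equivalent stand-ins.
- 2D gamma only; no film-scan processing or registration.
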