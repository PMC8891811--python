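# Methods

## Physical model

The solver computes the single-frequency (time-harmonic, e^{+iωt})
acoustic pressure field of a focused source radiating through water and
a stack of homogeneous tissue slabs, in axisymmetric cylindrical
coordinates (r, z):

∇·(−(1/ρ_c)∇p) − ω² p/(ρ_c c_c²) = 0.

Losses are carried by an equivalent-fluid complex representation: the
wavenumber is k = ω/c − i·α_Np, with α_Np = α_dB·ln(10)/20, the complex
sound speed is c_c = ω/k, and the density stays real (the standard
closure when a tissue is characterized by one attenuation number).
Nonlinearity, shear waves, mode conversion, tissue heterogeneity and
heating are outside the model: propagation is linear and compressional
in homogeneous slabs.

Material constants (1 MHz): scalp 1450 m/s, 68 dB/m, 955 kg/m³; skull
4080 m/s, 2000 dB/m, 1658 kg/m³; brain 1552 m/s, 85 dB/m, 1046 kg/m³.
Water is fixed at 1482 m/s, 998 kg/m³, 0 dB/m (295 K) so that the
free-field baseline is bit-stable; all constants live in a packaged CSV.

## Discretization

A conservative second-order finite-difference scheme on a uniform grid:
the 1/ρ_c coefficient is harmonically averaged at cell faces, which
enforces pressure and normal-flux continuity at layer interfaces; the
axis r = 0 uses the symmetric finite-volume limit (zero radial
derivative); layer interfaces snap to the nearest grid line (the default
sweep thicknesses are exact multiples of the spacing, so no snapping
error enters the identification).

Open boundaries are perfectly matched layers via complex coordinate
stretching, s = 1 − iσ/ω with a quadratic σ profile, one water
wavelength thick, graded for a theoretical round-trip reflection of
10⁻⁴.  A rigid wall closes the grid behind each layer.  Measured
boundary reflection in a 1-D water column is ~10⁻⁴ in amplitude.

**Grid spacing (default 0.05 mm, ≈30 points per water wavelength).**
Second-order stencils carry anisotropic numerical dispersion whose
angle-dependence acts as a defocus aberration on a converging beam; at
10 points per wavelength it displaces the focal maximum by several
millimetres and changes the focal peak by >2% on grid halving.  At
0.05 mm the free-water peak moves <0.3 mm relative to a semi-analytic
Rayleigh-integral oracle and changes 0.56% when the grid is halved.
This is the accuracy the attenuation statistics inherit.

**Source model.**  The focused bowl is realized as an equivalent source
plane: a phased annular aperture at the apex position whose spherical
phase converges on the geometric focus, imposed as a transparent volume
source.  A transparent source lets skull echoes pass into the bottom
absorbing layer instead of reverberating against a rigid cap, and keeps
the discrete operator free of interior Dirichlet rows (see below).  The
drive amplitude is fixed by calibration: one free-water solve and a
scalar rescale to the target focal pressure — exact by linearity.

**Direct solution.**  The slabs are radially uniform, so the operator
separates into a radial part (shared by all axial planes up to a 1/ρ_c
factor) and an axial part.  The default path diagonalizes the radial
operator once (dense complex eigendecomposition, cached across solves
that share a radial grid) and solves an independent tridiagonal axial
system per radial mode.  This is a direct, deterministic method that
agrees with sparse LU on the assembled matrix to ~10⁻¹³ relative, uses
a small fraction of its memory on fine grids, and turns a full
thickness sweep into a seconds-scale computation.  Sparse LU remains as
a residual-checked fallback.

## Transducer geometry

Center frequency 1 MHz, aperture diameter 46 mm.  The curvature radius
is not part of the published description; the default is 90 mm (F ≈ 2,
cone half-angle 14.8°).  The choice is physical, not free: the
water→skull critical angle is arcsin(1482/4080) = 21.3°, and any
curvature radius below ~63 mm pushes the marginal rays supercritical,
clipping several extra percentage points of transmission.  The published
simulated transmissions closely track sub-critical (near-normal) slab
transmission — a 1-D transfer-matrix sweep over the same thicknesses
fits to a decay of exactly 0.2537 mm⁻¹ — so the geometry is taken to be
weakly focusing.  Within the sub-critical regime the attenuation
percentages are insensitive to this parameter (a ±5 mm change moves the
5 mm skull attenuation by under 3 percentage points; asserted in the
suite); the insensitivity breaks down near and beyond the critical
angle, which is why the default keeps a comfortable margin.

The domain is 30 mm radially and 120 mm axially, so the focal region
(geometric focus ≈ 93.5 mm from the grid origin) and its half-maximum
tail precede the top absorbing layer.  Tissue stacks start 10 mm beyond
the source (the transcranial peak is always measured distal to the
stack, mirroring the hydrophone scanning above a slab resting on the
transducer); peaks are searched strictly beyond the last bone interface
plus a 1.5 mm margin, excluding standing-wave maxima at the interface.

## Attenuation statistics and identification

τ(z) = 100·P_z/P_water is the transmitted focal-peak percentage through
a skull slab of thickness z (mm); attenuation is 100 − τ.  Both are pure
ratios: drive level cancels by linearity, so one solve per geometry
covers every excitation level.  The identification sweep is 2.0–9.0 mm
in 0.5 mm steps (15 slab solves against one water baseline), spanning
all benchmark site thicknesses (3.5–7.1 mm).  The exponential law
τ = a·e^(−bz) is fitted by nonlinear least squares on τ itself, seeded
by a log-linear regression (which also serves as the fallback when the
nonlinear step fails); R² and per-sample residuals are reported.
Site-to-site prediction P_x2 = P_x1·τ(x2)/τ(x1) = P_x1·e^(−b(x2−x1))
depends only on b.

Relative errors against reference series use the model value as the
denominator, 100·|model − reference|/model, the convention that
reproduces the published per-site error figures.  Validation against
the packaged benchmark series uses the published coefficients
(61.85, 0.2537) by default so that the comparison is decoupled from the
local solver; `--refit` swaps in the locally identified law.

**Fit quality and the thickness resonance.**  A monochromatic slab is a
Fabry–Pérot cavity: transmission ripples with period λ_skull/2 ≈ 2.04 mm,
strongest where absorption is weakest (thin slabs).  The local sweep
therefore carries a genuine ±1–2 point ripple at 2–4 mm, capping the
exponential fit at R² ≈ 0.992 on the default grid; the independent 1-D
transfer-matrix oracle shows the same ripple (R² ≈ 0.972 at normal
incidence — the focused beam's angular spread partially smooths it).
A smooth exponential with R² > 0.999 is only attainable from data in
which this coherence is averaged out (e.g. broadband pulse peaks).  The
identified decay coefficient is insensitive to the ripple and lands
within ~13% of the published 0.2537 mm⁻¹.

## Synthetic data generator

`generate_tau_samples` draws τ_i = a·e^(−b z_i)(1 + ε_i) with
ε_i ~ N(0, σ), multiplicative noise emulating hydrophone amplitude
error (default σ = 1%), seeded and reproducible, clipped to [0, 100]
with a warning on clipping.  It emulates the *statistical* structure of
thickness–transmission observations, not the physics: it has no
thickness resonance, no angular effects and no systematic bias, so fit
recovery tests demonstrate the estimator (exact recovery at σ = 0;
unbiased recovery at the noise scale), not solver accuracy — that is
what the solver sweeps and oracles are for.

## Numerical choices and degenerate inputs

- Grid admission requires ≥8 points per wavelength in the slowest
  medium; the default is ~30.
- Fit admission requires ≥3 samples spanning >1 mm; a non-decaying
  sample set (e.g. slabs of the background medium, τ ≡ 100%) is flagged
  degenerate rather than fitted.
- FWHM uses linear interpolation of the half-maximum crossings through
  the peak; a contour leaving the grid flags the metric as truncated
  (NaN) instead of silently clipping.
- Peak searches on an empty region, zero reference pressures, zero
  model denominators and zero-variance correlation inputs raise
  immediately.
- Everything is deterministic: direct solves, no iterative methods, no
  randomness outside the synthetic generator's explicit seed.

## Problem sizes

Default solves use a 601 × 2401 (r × z) grid (~1.4 M unknowns), ~3 s
each with the structured path after the cached radial decomposition; a
full identification sweep is ~30 s; the grid-halving convergence check
(~5.8 M unknowns) runs in ~30 s within a few hundred MB of memory.

## Known limitations

- Homogeneous flat slabs: no CT-derived geometry, curvature or
  heterogeneity of real skulls; published phantom attenuations differ
  from flat-slab theory accordingly (the benchmark comparison shows
  up to ~6.6% disagreement at the thinnest site).
- Single frequency: broadband pulse peaks (as measured by a
  pulser/receiver + hydrophone) average over the slab resonance that a
  monochromatic model resolves.
- The equivalent-source plane reproduces the bowl's focal field in the
  paraxial sense; very strongly focused geometries (F < 1) would need
  the true cap geometry.
- The exponential law is an identified summary of one material/geometry
  family; its coefficients are not transferable to other frequencies or
  skull properties without re-identification.
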