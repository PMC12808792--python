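# Methods

`corneomech` implements a cellular-biomechanics measurement stack — AFM
Hertz stiffness estimation, traction force microscopy (TFM) and in-plane
intracellular stress recovery, morphometric/clinical scoring, and
exposure-cohort statistics — together with synthetic-data generators that
provide ground truth for every inverse stage. This note documents the
models, the numerical choices, and what the synthetic validation does and
does not establish.

## Coordinates and units

Gridded fields are indexed `[iy, ix]` with the physical y axis increasing
with the row index (origin at the lower-left corner); pixel `i` is centred
at `(i + 0.5) * pixel_size`. TIFF I/O flips rows so saved images follow the
top-row-first viewing convention. Positions and displacements are in
micrometres, moduli and tractions in pascals, forces in nanonewtons, AFM
lengths in nanometres.

## Half-space elasticity kernel

Substrate mechanics uses the tangential block of the Boussinesq/Cerruti
surface solution for a semi-infinite, homogeneous, isotropic elastic
half-space — the standard 2D TFM approximation that neglects normal
tractions and out-of-plane motion. The kernel is regular at ν = 1/2; the
incompressible limit needs no special casing.

Rather than sampling the analytic Fourier tensor at the grid wavevectors,
the package builds the discrete Green tensor as the DFT of the real-space
kernel *integrated analytically over each square grid cell* (the integrals
of 1/r, x²/r³, y²/r³ and xy/r³ over rectangles have closed antiderivatives).
Two consequences:

* the forward solve (`forward_displacement`) is the **exact** discrete
  convolution of a pixel-constant traction field with the continuum kernel —
  a concentrated load matches the closed-form Cerruti solution to ~0.02% on
  axis at r = 4 px, whereas the sampled analytic tensor loses ~3% there to
  Nyquist truncation of its slowly decaying 1/k tail;
* forward and inverse use the same tensor, so they are exact mutual
  inverses per wavevector on a periodic grid.

With `pad_factor ≥ 2` and the kernel built on the padded grid, every
source–target separation surviving the final crop lies in the unwrapped part
of the kernel, so padding eliminates (not merely suppresses) wrap-around in
the forward direction.

## FTTC inversion

`fttc_invert` inverts the 2×2 tensor per wavevector, optionally
Tikhonov-regularized as (GᵀG + (λ·g₀)² I)⁻¹ Gᵀ with g₀ the largest tensor
norm on the grid (λ is therefore dimensionless). The zero mode is set to
zero: rigid translation carries no traction information, and a cell in
equilibrium exerts no net force.

A measured field of view is aperiodic; re-padding a cropped displacement
field with zeros is inconsistent with the half-space solution and the λ = 0
inverse amplifies the seam into field-wide ringing (~45% RMS of peak on the
reference scene). Two measures fix this:

1. **Mirror padding** (symmetric extension, continuous at the seam) instead
   of zero padding (default `boundary="mirror"`);
2. **Richardson refinement** (default 5 iterations, λ = 0 only): each step
   computes the exact aperiodic forward model of the current traction
   estimate, inverts the residual spectrally and adds the correction. The
   iteration contracts geometrically (factor ≈ 0.55/step on the reference
   scene) toward the traction whose half-space displacement matches the data
   on the field of view; 5 steps reach 0.3% RMS of peak. Regularized
   solutions (λ > 0) are the plain spectral Tikhonov inverse — refining them
   would converge back to the unregularized solution.

`pad_factor=1` keeps the exactly periodic transform pair, used by the
round-trip tests. The L-curve helper (`suggest_lambda`) scans λ and returns
the curvature-corner candidate; the default remains λ = 0.

## Displacement correlation (DIC/PIV)

`cross_correlate_windows` estimates per-window displacement in two stages
(discrete window offset): a circular correlation of the co-located,
mean-subtracted windows gives the integer displacement; the post window is
then re-cut at that integer offset — so the residual correlation peak is
symmetric about zero — Hann-apodized, and refined with a three-point
Gaussian subpixel fit (parabolic fallback for non-positive neighbours). The
re-cut repeats (≤3 times) while the residual retains an integer part.
Without the re-cut, content entering/leaving a co-located window biases the
peak by a few tenths of a pixel at multi-pixel displacements; with it,
integer shifts are recovered exactly away from the image border and a
0.30 px shift is recovered with ≈0.016 px MAE on clean bead images.

Hygiene follows standard PIV practice: the normalized-median outlier test
over 8-neighbourhoods (`filter_outliers`, threshold 2, ε = 0.1 px), linear
gap interpolation (`interpolate_gaps`, exact on linear fields, ≥50% valid
required), and optional Gaussian smoothing of the vector grid
(`smooth_field`). When windows overlap by more than half, adjacent nodes
share most of their content and the grid oversamples the window-limited
resolution; smoothing at sub-window scale (default σ = 0.8 node spacings)
suppresses node-to-node noise that a λ = 0 inversion would otherwise amplify
at the grid Nyquist. The reference TFM chain uses window 32 px, overlap
24 px, smoothing 0.8 — peak traction recovery is then within ±5% across
render seeds.

## AFM Hertz fitting

Model: rigid cone of semi-included angle θ on an incompressible elastic
half-space, F = E·tan θ / (√2 (1 − ν²)) · δ², with indentation δ = Z − d
(piezo extension minus deflection) and force F = k·d. Defaults: θ = 35°
(the probe's nominal tip geometry is pyramidal; the conical form is used
with a representative half-angle, configurable), ν = 0.5 (fixed — ν and E
are jointly unidentifiable in this model), k = 0.08 N/m, fit window
0 ≤ δ ≤ 600 nm. The model is linear in E, so the windowed least-squares fit
is closed-form.

Only the approach segment is used (split at the global maximum of Z); the
baseline is a linear fit to the first 25% of the approach, subtracted.

**Contact point.** The default detector scans candidate contact points on a
10 nm grid, scoring each by the full-curve residual of a piecewise model
(zero deflection before contact, Hertz onset after, E closed-form per
candidate), then refines the best candidate by bounded 1-D minimization.
Two details matter: the residual must extend the fitted model over the
*entire* curve — a residual confined to the fit window drops high-force
samples for late candidates and is not comparable across them — and
variance-based detectors (the classic ratio-of-variances method, available
as `method="rov"`, and threshold crossing, `method="threshold"`) lag the
true contact by ~170 nm on soft samples because the quadratic onset climbs
out of the noise only gradually. The chosen method is recorded in the fit
result. Measured on the generator at 2 kPa / 20 pN force noise: 100% of
replicates within 20 nm; at 50 pN the mean modulus bias is ≤0.4% across
0.5–10 kPa.

Per-cell aggregation of replicate curves (typically three) uses the mean by
default; the median is available (`rule="median"`).

## Intracellular stress recovery

The cell is modelled as a thin plane-stress linear-elastic sheet of unit
reference thickness occupying the cell footprint. The traction t the cell
exerts on the substrate returns to the sheet as the reaction −t, entering
equilibrium ∇·σ + (−t) = 0, i.e. ∇·σ = t, with a stress-free cell edge.
Discretization: bilinear quadrilateral elements on the traction grid (one
element per cell, 2×2 Gauss), stresses at element centres — the stress grid
is congruent with the traction grid. The pure-Neumann null space (two
translations, one rotation) is removed by Lagrange constraints. The sheet's
Young's modulus only scales the unreported displacements; the reported
stress summaries change by <10⁻¹⁰ under a ten-fold modulus change. Sheet
ν defaults to 0.5. A non-equilibrated traction (net force > 1% of Σ|t| dA)
triggers a warning and mean removal; mask holes are filled with a warning.

The 1D validation fixture is a contractile strip with traction linear in x,
t(x) = t₀(1 − 2x/L), whose axial tension integrates to the parabola
σ(x) = t₀(x − x²/L): midline t₀L/4, spatial mean t₀L/6. The solver
reproduces both to <0.01% on a 256×8 strip, with an interior equilibrium
residual (central-difference divergence vs applied traction) of 0.06% RMS.
Tension summaries report both the monolayer-stress convention
(mean of (σ₁+σ₂)/2) and the mean/max of the largest principal stress; on a
uniaxial strip the 1D closed form corresponds to the principal-stress
quantities (σ₂ ≈ 0), which is what the strip checks assert.

## Morphometrics and clinical scores

Circularity is 4π·area/perimeter². Area is pixel count × pixel area;
perimeter uses the 4-direction Crofton estimator, chosen because naive
boundary counting overestimates smooth perimeters enough to push a disc's
circularity below 0.9, defeating the isoperimetric sanity check (Crofton
gives 0.99–1.00 for discs of r ≥ 50 px; note it *under*-estimates axis-
aligned squares, so closed-form shape checks use analytic perimeters).
Hydration rate is (wet − dry)/wet × 100%. Fluorescein grading: fusion → 3;
otherwise 0 stains → 0, 1–30 → 1, >30 → 2. The nuclear/cytoplasmic ratio is
the ratio of mean intensities over disjoint masks; a constant background b
shifts it to (μ_N + b)/(μ_C + b), so background handling belongs upstream.

## Cohort statistics

Exposure groups follow the daily-mean PM2.5 thresholds of the Chinese
Ambient Air Quality Standards: ≥ 75 µg/m³ high, < 35 µg/m³ low, otherwise
excluded. Group comparisons use Welch's unequal-variance t test by default
(pooled available by flag); associations use Spearman rank correlation with
average ranks for ties. Per-parameter p values are reported uncorrected,
matching per-parameter reporting practice, with a Benjamini–Hochberg column
alongside. Calibration on simulated cohorts: null rejection 0.050 ± 0.005
at α = 0.05 (2000 replicates, n = 20/20); power ~100% for a 0.8-SD shift at
n = 100/100.

## Synthetic data: what it does and does not emulate

The generators define the validation conditions:

* **Traction scenes** — sums of Gaussian patches, net-force-balanced by
  subtracting the area-weighted mean. The reference scene is a contractile
  dipole (256², 0.2 µm/px, two 300 Pa patches of σ = 5 µm pulling inward,
  24 µm apart) on the default substrate (E = 10 kPa, ν = 0.45 — typical
  soft polyacrylamide; the substrate constants are configurable
  assumptions, not measured values). Peak substrate displacement ≈ 0.45 µm
  (~2.3 px), typical of soft-gel TFM.
* **Bead images** — uniformly random beads, symmetric Gaussian PSF
  (σ = 1.5 px default), additive Gaussian noise and constant background;
  default density 0.05 beads/px² (≈13 beads per 16×16 window). No
  photobleaching, drift, out-of-focus blur or bead aggregation.
* **Force curves** — 500 nm/s ramp, 1.7 kHz sampling, 1.2 µm loading
  displacement; the post-contact deflection solves the implicit contact
  relation exactly, so generator and fit share no code path beyond the
  printed force law. Baseline slope, contact offset and white force noise
  are modelled; viscoelasticity, adhesion and hydrodynamic drag are not.
* **Cohorts** — normal per-parameter draws with group means/SDs and uniform
  PM2.5 within group ranges; defaults n = 113 (high) / 105 (low). Real
  Corvis ST parameters are correlated; the generator draws them
  independently, so multivariate behaviour is not validated.

Passing the synthetic suite establishes that each inverse stage recovers
known ground truth under these idealized conditions. It does not establish
accuracy under optical aberrations, substrate nonlinearity or
finite-thickness gels (no finite-thickness correction is implemented), nor
the clinical validity of any threshold.

## Problem sizes

The validation suite uses 256² traction grids, 100 noisy force-curve
replicates per modulus (three moduli), 200-replicate contact-point and
power Monte-Carlos, and 2000-replicate null calibration — sizes at which
every recovery statistic above is stable to well within its acceptance
band while the whole suite runs in minutes on one core.

## Known limitations

* 2D tangential TFM only: no z-displacements, no finite-thickness
  correction, no constrained/BEM traction methods.
* λ = 0 inversion is exact but noise-faithful; the smoothing/regularization
  trade-off is exposed (`smooth_field`, λ, `suggest_lambda`) rather than
  decided.
* The stress recovery assumes a linear-elastic, isotropic, simply connected
  sheet; active prestress and viscoelasticity are outside the model.
* Contact-point detection assumes a single contact with a clean pre-contact
  baseline; curves with snap-in adhesion need the withdraw segment, which
  is deliberately unused.
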