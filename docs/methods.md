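# Methods

## The measurement model

A tubule of diameter D far below the optical resolution cannot be resolved,
but its two dye signals scale with different geometric measures: the
luminal volume dye integrates over the cross-sectional area (π D²/4 per
unit length) and the membrane dye over the perimeter (π D per unit length).
After convolution with a *spherically symmetric* Gaussian PSF of standard
deviation σ, the centerline values of the two channels are

    volume:    V(0)  = 1 − e^(−x),          x = a²/(2σ²),  a = D/2
    membrane:  M(0)  = (a/σ²)·e^(−x)        (per unit surface density)

The normalization conventions make these dimensionless: the volume channel
is scaled so the bath (pure extracellular dye) reads 1, and the membrane
channel so the surface sarcolemma (a plane of unit surface density, whose
blurred peak is 1/(σ√2π)) reads 1.  The channel ratio at the centerline is
then

    V:SA(D) = σ·(e^x − 1) / (a·√(2π))

whose leading term is the linear law

    V:SA ≈ (D / (2·FWHM))·√(ln 2/π),    FWHM = 2σ·√(2 ln 2)

This linear form is the field's calibration equation; its slope at
FWHM = 0.6015 μm is 0.39 μm⁻¹.  Two conversions are provided:

* `vsa_to_diameter(v, fwhm)` — the linear law, exact arithmetic, used for
  the published calibration identities (the rabbit pair V:SA 0.139 ↔
  0.356 μm and the mouse pair 0.066 ↔ 0.169 μm imply the same FWHM to four
  significant figures, which is how the package's calibration closure test
  works).
* `vsa_to_diameter(v, fwhm, model="cylinder")` — numerical inversion of
  the full blurred-cylinder law (Brent bracketing, xtol 1e-12).  The linear
  law under-predicts V:SA by ~10% at D = 0.36 μm and ~30% at D = 0.5 μm
  (FWHM 0.6 μm), so the pipeline defaults to the cylinder inversion; on
  noise-free phantoms this recovers D ∈ [0.1, 0.5] μm within ±3%.

The ellipticity correction solves, in closed form, for the ellipse with
minor/major ratio E whose area-to-perimeter ratio matches the circular
model's D/4: the major semi-axis is p = D·Ell(1−E²)/(πE) with Ell the
complete elliptic integral of the second kind.  At E = 0.75 and circular
D = 0.356 μm this gives axes 0.417/0.313 μm; published rounded values of
0.40/0.32 μm differ from the pure area-perimeter matching solution by ~4%,
and both are noted rather than reconciled, since the original ellipse
calculation is not specified.

## Why PSF symmetrization

A confocal PSF is ~2.4× wider axially than laterally.  The blurred
intensity of a thin tubule then depends on its orientation relative to the
optical axis, not only on its size.  Blurring the data laterally by
σ_extra = √(σ_z² − σ_xy²) (widths add in quadrature) makes the effective
PSF spherical with FWHM equal to the raw axial FWHM; after this step the
recovered diameter of a 0.3 μm phantom tubule differs by <3% between
transverse and axial orientations, while without it the raw V:SA readings
differ by well over 5% (both are asserted in the test suite).  The FWHM
entering the conversion equations is always the symmetrized one.  The
method assumes z is the worst axis; a PSF with finer axial than lateral
resolution is rejected rather than silently reinterpreted.

`measure_psf` estimates the raw FWHMs from a bead stack by per-axis
Gaussian fits through the intensity centroid, removing the finite bead
size by quadrature with the sphere's equal-second-moment Gaussian width
(σ_bead = d/(2√5)).  On rendered 0.17 μm beads the round-trip error is
under 3% per axis.

## Processing order and normalization details

The fixed order is: background subtraction → symmetrization blur →
normalization.  Background over the cytosol is the median-smoothed image
itself (radius 2 voxels, configurable); at TT-skeleton voxels — and at all
other cell voxels outside the cytosol mask — it is nearest-neighbor
interpolated from the cytosol in physical-unit Euclidean distance, with
exact-distance ties broken toward the lowest (z, y, x) index.  The cytosol
mask excludes a one-FWHM band around both the TT skeleton *and* the cell
boundary: voxels there carry blur tails of genuine structures (tubule,
surface membrane, bath), and treating those tails as background dents the
SS reference peak after re-blurring (~35% low in experiments during
development), destroying the calibration.  The volume channel is
background-subtracted only inside the cell, since its bath signal is the
normalization reference, not background.

Negative intermediate values are preserved so that subsequent blurs average
correctly; clipping to zero happens only when the final ratio is formed.
Normalization constants are trimmed means (central 80%) of the bath voxels
and of the SS-skeleton voxels.  Both normalizations make the result exactly
invariant to detector gain on either channel (asserted to 1e-10).

Voxels whose normalized membrane signal falls below a floor (default 0.1,
i.e. 10% of the SS reference) are excluded from the V:SA map and counted in
the provenance record, guarding the division.

## Segmentation

* Cell/bath: Otsu threshold on the volume channel; the cell is the
  below-threshold side after an anisotropy-aware morphological closing
  (default radius 0.3 μm; the input is edge-padded so closing cannot eat a
  rim at stack faces) and largest-component selection; the bath is the
  complement eroded away from the cell by one symmetrized FWHM.
* SS skeleton: cell-boundary voxels (stack faces excluded) passing three
  filters — strong gradients in both channels (Otsu cutoffs on the boundary
  gradient population), boundary normal within 60° of the lateral plane
  (rejecting out-of-focus top/bottom caps), and low mean curvature
  (rejecting z-groove mouths) — then snapped to the membrane-channel peak
  within ±2 voxels along the normal, so the reference samples the true
  blurred-plane maximum rather than a threshold-offset surface.
* TT skeleton: Otsu threshold of the membrane channel computed *within the
  deep cell interior* (one FWHM in from the boundary; a global threshold
  would sit above faint tubule signal because the SS dominates the
  histogram), thinned to one-voxel lines, end-reclaimed (below), restricted
  to the deep interior, SS removed, spurs shorter than 2 voxels pruned.  A
  contrast floor (threshold ≥ 5% of the image maximum) prevents a
  featureless interior from yielding a spurious skeleton.
* Cytosol: cell minus one-FWHM dilations of TT skeleton and boundary.

### 3D thinning

The package ships its own topology-preserving curve thinning
(`ttvsa._thinning`): border-sequential peeling over the six face
directions, deleting only voxels that are *simple points* under the exact
(26, 6) connectivity characterization — removal keeps exactly one
foreground 26-component in the punctured 3×3×3 neighborhood and exactly one
background 6-component touching a face neighbor — and never deleting curve
endpoints.  Candidates within a pass are processed in 8-subfield (parity)
order with re-checking against the current state; plain scan order lets a
bar of even cross-section pass through a two-voxel-wide state in which
sequential deletion retracts the whole bar from one end while remaining
locally simple at every step, and the parity interleaving leaves
non-simple bridges that pin the geometry.  The result is idempotent,
preserves topology (a solid torus thins to a closed loop), and keeps
straight tubes at full length within ±2 voxels.

Thinning still retracts open tube ends by a few voxels before the endpoint
guard engages, so skeleton tips are extended back through the binary mask
along their incoming direction (estimated from a 6-voxel back-path to avoid
following a diagonal last step).  Without this, skeleton length densities
read ~10% low.

## Network geometry

Skeleton length sums physical 26-neighbor step lengths (anisotropy-aware).
Local orientation is the principal eigenvector of the structure tensor of
skeleton coordinates within a spherical window, angle mapped so 0° is the
transverse plane and 90° the cell's long axis; the window radius defaults
to 0.75 μm — above the symmetrized FWHM, so skeleton wiggles at blur scale
average out (at 0.5 μm these misclassify ~5% of length as oblique on
construction phantoms).  Orientation fractions are length-weighted (each
voxel weighted by half its incident edge lengths) with class intervals
closed at ±15°.  The cell's long axis comes from the mask's principal
component, overridable in config; phantom runs use the scene's declared
axis.  Derived fractions are cylinder arithmetic: area density πD̄L, volume
fraction (πD̄²/4)L, with the identity volume/area = D̄/4.

## Cable properties

R_m = R_input·(C_cell/C_specific) with explicit unit conversions
(45 MΩ, 150 pF, 1 μF/cm² → 6.75 kΩ·cm²); λ_dc = √(D·R_m/(4R_L)) computed
in cm and returned in μm; under sinusoidal drive λ_f = λ_dc/Re{√(1+iωτ_m)}
with τ_m = R_m·C_specific.  The real-part reading is the default because it
reproduces the expected ~50% shortening at 150 Hz with τ_m ≈ 7 ms; the
modulus reading (~61%) remains selectable.  λ_f/λ_dc depends only on the
product f·τ_m, asserted as a property test.  The detubulation
extrapolation divides the observed capacitance drop by the fraction of
tubules disconnected; if the extrapolated tubule capacitance exceeds the
total, the fraction is capped at 100% with a warning.

## The phantom generator

The generator emulates the study conditions: 60 nm lateral / 180 nm axial
voxels, a half-space cell with optional sinusoidal z-groove corrugation at
sarcomere spacing (1.8 μm), straight-or-polyline tubules with circular or
elliptical cross-sections (area-preserving, E = minor/major), a bath volume
dye filling extracellular space and lumina, and a membrane area-density
field on surface and walls.  Rasterization is sub-voxel: per-axis
supersampling chosen so fine samples are ~isotropic (3 per smallest voxel
edge by default), an antialiased lumen indicator (linear ramp over one fine
sub-voxel), and a thin membrane shell renormalized so its integral equals
the true area times surface density — the nominal shell thickness cancels
exactly, and integrated lumen volume and wall area match the analytic
cylinder values within 1%.  Tubules are open cylinders (flat ends, no cap
membrane), so π·a·b·L and P(a,b)·L are exact truths.  Both channels are
blurred with separable Gaussian kernels truncated at 4σ with replicate
padding (flat far fields stay flat, protecting the normalization regions);
noise (none / additive Gaussian / Poisson with a photon-count scaling,
default 500 counts per intensity unit) is applied after the blur from a
seeded generator, so output is bit-reproducible.

Default amplitudes set both dyes to unit brightness; relative dye
brightness and detector noise are free parameters of the instrument, not of
the method, and acceptance scenes use the noise-free setting.

What the phantoms do *not* emulate: real TT networks' branching, dilations
and spacing irregularity; refractive-index aberrations or depth-dependent
PSFs; dye binding heterogeneity and channel crosstalk; motion.  Passing
tests therefore demonstrate the correctness of the measurement chain under
its stated optical model, not robustness to every property of live-cell
data.

## Problem sizes and numerical choices

Validation scenes use a 128×128×48 frame at the standard voxel sizes
(lateral field trimmed from the full 256×256×64 acquisition frame; all
physical scales identical), with single tubules of 4.7–6.6 μm length or a
four-tubule network, chosen so that tubule separations (≥1.7 μm) exceed
the blur's merging distance — closer tubules fuse into one mask component,
which is a physical limitation of the method, not a code path under test.
The cylinder-recovery series covers D ∈ {0.1, 0.17, 0.25, 0.36, 0.5} μm at
symmetrized FWHM 0.6 μm.  Histogram bin width defaults to 0.01 V:SA units.
Mann-Whitney comparisons use the exact null for groups of ≤8 without ties
and the tie-corrected normal approximation otherwise; the variance-ratio F
test is two-sided.

## Known limitations

* Two closely apposed fine tubules and one flattened wide tubule are
  indistinguishable by V:SA alone.
* The diameter map assigns each skeleton voxel the conversion of its local
  ratio; near junctions the ratio mixes contributions of both branches.
* End voxels of a tubule read slightly low (the lumen ends but the blur
  window extends past it); with the membrane floor and the deep-cell
  restriction this contributes <2% to tubule means at the default scene
  sizes.
* The cylinder inversion assumes a circular cross-section; for known
  ellipticity the closed-form axis correction applies afterwards.
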