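# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `torusalign`.  It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate and unit conventions

Volumes are indexed `(z, y, x)`, 0-based, voxel-center origin.  Lateral
sampling must be isotropic (`dy == dx`, enforced at ingest); axial sampling
may be coarser.  All geometry — ring poses, crossings, rotations — lives in
isotropic *lateral-pixel* units, with slice indices converted via the voxel
aspect `dz/dx` at module boundaries.  This keeps the ring model an exact
circle regardless of z anisotropy and avoids half-pixel drift between the
fit and the resampling transforms.  Angles are radians internally; degrees
appear only in user-facing output and the CLI.  Physical lengths are nm.

## The tilted-ring model and its crossings

The ring is a perfect circle parameterised by travel angle ρ (see the
README for the parametric form).  Its pose has six parameters: center
(xc, yc, zc), radius r, tilt θ ∈ [0, π/2) from the image plane, and azimuth
φ ∈ [0, 2π).  For θ = 0 the azimuth is unidentifiable (the flat circle is
rotation-invariant); the fit handles this by gridding φ and flagging
`phi_undetermined` when the grid costs are flat to within 1% (relative
spread, configurable).

The crossings of the ring with a vertical plane through the guessed center
satisfy `A sin ρ + B cos ρ + C = 0` with plane-specific coefficients.  The
production solver uses the harmonic-addition identity
(`R sin(ρ+δ) = −C`, δ = atan2(B, A)), which is branch-safe and has no
singular divisions; both solutions are verified by substitution into the
ring model and returned in stable order (the crossing on the plane's
positive half-axis first, ties broken by increasing ρ), so paired spots are
never swapped between fit iterations.  The classical dimensionless
intermediates `a_P`, `c_P` (the tan⁻¹ formulation, which divides by factors
like cos θ cos φ) are computed and reported for reference, as NaN where
their denominators vanish.  Plane naming follows the cross-section
convention in the source imagery: plane "xz" is {x = 0}, "yz" is {y = 0},
"45" is {x = y}, "135" is {x = −y}, all relative to the guess center.

An independent brute-force solver (dense ρ grid, default 2²⁰ points, plus
bisection refinement to 1e-12) shares the same contract and serves as the
oracle in the test suite; a closed-form chord solution covers the flat
(θ = 0) limit.  The acceptance run checks all three routes agree (analytic
vs brute force to < 1e-6 rad over 500 random poses; flat limit to 1e-9 px).

## Cross-section extraction and initialisation

Four strips through the guessed lateral center at 0°, 45°, 90° and 135°,
each sampled at 1-px lateral spacing over all z slices, bilinearly
interpolated, and averaged over a 2-pixel width (two parallel lines offset
±0.5 px).  Extraction is linear in the source volume.  The default strip
half-length is 1.5× the initial radius estimate.

Initialisation from the four clicked crossing points: radius = half the
mean of the two opposite-point distances, lateral center = centroid, z
center = argmax of the averaged z-intensity profiles at the four points
(restricted to ±5 slices of the optional z hint), θ₀ = 0.  Collinear or
coincident points are rejected.

## The constrained global fit

Each cross section carries two spots; all eight are asymmetric 2D Gaussians
with **one** shared lateral σ and **one** shared axial σ (the microscope's
resolution proxies), amplitudes per spot, and one additive baseline per
section (nonzero cytoplasmic background).  Spot centers are not free: they
are the plane crossings of the current pose, so the global fit couples the
eight spots through (xc, yc, zc, r, θ, φ).

Constraints (active bounds are reported as flags on the result):

* lateral center within 20% of the guess radius of its initialisation,
  applied per axis (a box, the smooth approximation of the stated disc);
* radius within a factor 2 of its initialisation;
* z center within one slice of its initialisation (slice units of the
  input volume);
* θ < 45°;
* amplitude pairs within 2× of each other, parameterised as pair-mean ×
  ratio with the ratio bounded to [1/2, 2] (smooth and bound-respecting);
* σ bounds [0.5, 30] px.

φ is fixed on a 10° grid (36 values).  Per grid value the fit uses
variable projection: for given nonlinear parameters the amplitudes and
baselines are linear, so each section's three linear coefficients are
solved exactly via its 3×3 normal equations and the optimiser (L-BFGS-B,
warm-started along the grid) sees only the 7 nonlinear parameters.  A
cheap radius scan (25 values across the bound interval) precedes the grid
so a badly initialised radius cannot strand the optimiser on a gradient
plateau.  The winning φ gets a trust-region least-squares polish and then
a final fully parameterised bounded fit (pose + σs + pair-means + ratios +
baselines) that enforces the amplitude-ratio constraint exactly.
Termination: relative tolerances 1e-10 to 1e-12; uniform (unweighted)
least squares — the source volumes are reconstructed images whose noise is
not Poisson-distributed in any calibrated sense, so uniform weighting is
the neutral choice.  Baselines are fitted, not pre-subtracted.

`fit_quality` is the machine surrogate for visual inspection: it renders
the model cross sections next to the observed ones and passes the fit when
the residual RMS is below a configurable fraction (default 0.3) of the
peak fitted spot amplitude.

## Realignment and averaging

The flattening transform rotates the volume by −φ about z, then −θ about
the in-plane axis, about the fitted center (rotations composed in physical
space so z anisotropy is honoured), then translates the center to the
center of a fresh canvas: an odd lateral square of 2.5× the fitted diameter
(configurable) so "the center" is a single voxel, with the source slice
count (odd-ified) in z.  Resampling is trilinear, keeping the stage linear;
spline interpolation exists but is off by default.  Integrated intensity is
conserved to well under 1% for content inside the canvas.

In-plane rotations: uniform-random (integer-seeded, reproducible) to wash
out non-aligned ring gaps, or oriented so the vector from the ring center
to a secondary-channel reference point lands on +y ("up") or +x
("sideways") — used for species with an asymmetric lobe (half-bridge-like
distributions) before averaging.

Averaging is the voxelwise mean.  With outlier normalisation enabled, a
particle whose integrated intensity exceeds 3× the median of the *other*
particles' integrals is rescaled to that median first.  The leave-one-out
median is deliberate: with a plain median a single dominant particle
inflates the reference and can escape its own normalisation.  When no
particle trips the threshold intensities are averaged raw.

## Metrology

Radial profiles sample expanding circles at ≈1-px arc spacing (bilinear
interpolation) and average per integer radius, on the central z slice by
default.  Diameters come from the vertical and horizontal line profiles
through the map center (3-px averaged bands): each profile is fit to two
Gaussians with shared width and constant baseline, and the component
diameter is the distance between the fitted centers.  Profiles whose
fitted peak separation falls below 1.2σ (or whose halves have no distinct
peaks) raise a below-resolution error rather than returning a number.
If the two components agree within 5% (configurable) the ring is reported
symmetric with their mean and quadrature/2 error propagation; otherwise
both components are reported separately (asymmetric rings).

**Monte Carlo errors** are a residual-calibrated parametric bootstrap: the
per-point noise SD is the SD of the fit residuals, replicate profiles are
model + Gaussian noise at that SD, each replicate is refit, and the SD of
the replicate diameters is the reported "±".  Reported values are the SD
(not SEM) of the bootstrap distribution, and condition comparisons use a
two-sample two-tailed t-test on the bootstrap distributions.  The bootstrap
assumes homoscedastic profile noise; heavy clipping at zero background
would violate it, which is why averaged maps retain their (positive)
background pedestal.

Fiducial normalisation rescales a sample diameter by (reference /
measured) of a co-imaged fiducial ring of known size, with relative errors
combined in quadrature — this transfers diameters across strains and
imaging batches sharing the fiducial channel.

Ring/bridge flux partitioning works on the z-projected image with two
disjoint user-supplied masks (annulus/disk and sector primitives, or raw
boolean arrays).  Background is the histogram mode of pixels outside both
masks; fractions are background-subtracted mask integrals normalised to
their sum, so they always sum to 1.  The default simulation masks (full
disk to 1.25 r for the ring; a ±35° sector beyond it for the bridge) are
documented in `validation.bridge_partition_recovery`.

## FRET quantification

Efficiency convention (the standard for acceptor photobleaching):
`E_raw = (D_post − D_pre)/D_post` per punctum, donor intensities
background-subtracted and integrated over the punctum's grown region
(integration, not peak values, is the default).  Pipeline: Gaussian blur
(σ = 1 px) → local-percentile background subtraction (20th percentile,
31-px window) → local maxima above 8 robust noise SDs → adaptive region
grow (8-connected, ≥ 0.5× the peak, ≤ 200 px, with a descent constraint so
regions never climb into a neighbouring spot, and brighter maxima claim
contested pixels first, keeping regions disjoint).  Pre/post registration
is a global phase-correlation translation; each punctum's local
displacement is re-measured in a ±6 px window and puncta deviating > 2 px
from the global shift are flagged moved and excluded (cells whose
structures moved during the bleach cannot be quantified).

Group statistics against donor-only controls (which calibrate donor
photobleaching b during the acceptor bleach, and whose raw efficiencies
are slightly negative, ≈ −b/(1−b)):

* `relative_efficiency = mean(E_pair) − mean(E_control)` — the plain
  control subtraction.  It preserves the sign structure (can be negative)
  but retains a residual multiplicative bias of E·b/(1−b) (≈ +0.021 at
  E = 0.40, b = 0.05) because donor bleaching acts multiplicatively.
* `corrected_efficiency = 1 − (1 − mean E_pair)/(1 − mean E_control)` —
  the ratio form, exactly unbiased under multiplicative donor bleaching.
  This is the package's headline estimate of E; both are always reported.

Errors combine the two group SEMs in quadrature; significance is a
two-sided two-sample t-test of the per-punctum efficiencies.

## The scene simulator

`simulate_toroid_volume` renders a uniform line emitter along the ring
(≥ 64 sub-pixel samples per pixel of arc, trilinearly splatted), convolves
with an anisotropic Gaussian PSF, optionally adds a bridge blob (a
Gaussian cloud offset in the ring plane along the axis that flattens onto
+x) and uniform point-like background puncta, then applies Poisson photon
noise and Gaussian read noise from one integer-seeded generator (bit
reproducible per seed).  `simulate_fret_series` lays donor spots on a
jittered grid with per-spot flux variation; pre intensities are quenched
by (1−E), post intensities carry the de-quenching rise 1/(1−E) attenuated
by donor-only bleaching (1−b), with Poisson + read noise and an optional
global translation to exercise registration.

Standard scene conditions (used by the validation experiments and the
presets): lateral voxel 2 nm, axial voxel 6 nm, PSF σ = 2 lateral px and
6 slices axial, photon budget 4×10⁶ per scene, read noise SD 3.  These are
pixel-scaled conditions: ring radii of 30–60 px (diameters 120–240 nm at
this scale, with 90–170 nm conditions at radii 22.5–42.5 px) against a
sharpened PSF, preserving the anisotropic-spot structure of
SIM-reconstructed volumes while keeping every spot pair resolvable in a
single scene.  Peak SNR at these settings is ≈ 12–17 (the analytic
prediction `predicted_peak_snr` is verified empirically in the suite).

What the simulator does **not** emulate: structured-illumination
reconstruction artifacts (Wiener ringing, honeycomb patterns), correlated
reconstruction noise, incomplete/punctate rings, chromatic or stage drift,
and true instrument-scale resolution (≈ 100 nm lateral FWHM, at which a
90 nm ring is not two-peak resolvable in a single profile — the real
workflow leans on averaging and fiducial normalisation there).  Passing
recovery tests on these scenes therefore demonstrates the correctness of
the geometry, fitting, resampling and statistics, not the resolving power
of the microscope.

## Validation problem sizes

The acceptance experiments use: 500 random poses for solver agreement; 50
scenes for pose recovery (r ∈ [30, 60] px, θ ∈ [0°, 40°]); 20 particles
per condition for end-to-end metrology at 90/135/170 nm-equivalent
diameters with 200 bootstrap replicates; 200 independently noised maps for
bootstrap calibration at two noise levels; 20 scenes for the 45/55
ring/bridge split; 100 spots per group for FRET.  These sizes give stable
medians and fractions while keeping a full validation run to a few minutes
on one CPU.

## Known limitations

* The fit assumes one ring per crop; overlapping particles are not
  segmented.
* The φ grid resolves the azimuth to 10°; sub-grid φ refinement is not
  attempted (matching the discrete scan used in practice).
* The amplitude-ratio constraint makes the final fit non-smooth at the
  ratio bounds; active bounds are flagged rather than penalised.
* Monte Carlo errors quantify profile-noise uncertainty only; they do not
  include particle-selection or alignment variability across repeats.
* The center-bound is a per-axis box rather than the stated disc, so the
  reachable corner distance is √2× the nominal 20% — flagged fits should
  be inspected either way.
* Masks for flux partitioning are user inputs; the defaults documented
  above suit the simulated geometry and will need adjustment for real
  bridge morphologies.
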