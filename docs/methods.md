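# Methods

## Model overview

`valvemorph` couples three pieces of analysis around the mechanics of the
embryonic heart tube at the onset of valve formation:

1. a 2D zero-Reynolds-number simulation of a valveless pumping heart tube
   with deformable red blood cells (RBCs);
2. a decomposition of the wall shear stress (WSS) into its time average
   `tau0`, the harmonic amplitudes `tau1, tau2, ...` of its phase average,
   and the nonperiodic residual `tau'`;
3. quantification of tissue convergence from two-timepoint 3D stacks of a
   photolabeled tube (unfolding, per-azimuth gap length `L`, shortening
   factor `(L2 - L1)/L1`), with per-quadrant group statistics.

## Flow model

The heart is idealized as a 2D channel, periodic in the axial coordinate
`x` with period `length`, bounded by an upper and a lower wall.  The rest
half-width `h0(x)` carries three labelled segments — atrium, a narrowed
atrioventricular canal (AVC), and ventricle — joined by C2 (quintic
smootherstep) transitions; curvature-continuous walls matter, because
curvature jumps excite point-to-point oscillations in the boundary-integral
traction.

Everything is nondimensional: lengths in chamber rest half-widths, time in
beat periods (`f1 = 1`), viscosity `mu = 1`.  Stresses are therefore in
units of `mu * f1`, and profile plots are additionally offered normalized
by the spatial mean of `tau1`.  At the Reynolds number of the embryonic
heart (Re < 1) inertia is negligible and the instantaneous Stokes equations
apply; no inertial term exists anywhere in the solver.

### Wall kinematics

Each wall station oscillates harmonically: the inward displacement is
`(|m| + Im[m(x) e^{2 pi i f1 t}]) / 2` with a complex profile
`m(x) = a(x) exp(-i phi(x))`.  The profile is stored as its real and
imaginary parts on a dense grid — amplitude and phase interpolate badly
across phase branch cuts, the components of `m` are smooth and periodic.
Tabulated `(x, a, phi)` profiles are accepted; serialization is bit-exact.

**Volume closure.** In a periodic tube, incompressibility requires the
total enclosed area to be constant in time, i.e. `integral m(x) dx = 0`.
Arbitrary two-bump phase-lagged presets violate this, and a single-layer
Stokes representation then has no solution (the layers cannot create net
volume); the preset therefore subtracts the residual integral, spread
proportionally to the local amplitude, which closes the volume budget
exactly while perturbing the profiles by a few percent.

**Default preset.** The shipped "two-chamber pump" is a peristaltic
traveling wave: the whole moving span (atrium through ventricle; the
outflow–inflow junction stays motionless) oscillates with base amplitude
0.3, the AVC adds 0.2 so that its *relative* occlusion is strongest, the
phase advances linearly by `2 pi * 0.8` over the period (so the ventricle
lags the atrium and the contraction wave runs atrium -> AVC -> ventricle),
and the AVC leads the local wave phase by 1.4 rad.  Geometry defaults:
length 10, chamber half-width 1, AVC half-width 0.35.

These four numbers were chosen, once, by a lubrication-theory analysis of
the time-averaged stress (below) followed by full-solver verification, as
the minimal kinematics that reproduces the in-vivo regime: net
atrium-to-ventricle pumping with within-beat flow reversals in the AVC,
`tau1` maximal inside the AVC, and `tau0` negative on the atrial flank and
positive on the ventricular flank.  Two structural facts constrain any such
preset:

* for single-phase (standing) wall motion the time-averaged WSS vanishes
  *identically* (linearity of Stokes flow plus time-reversal symmetry), so
  `tau0` patterns are pure rectification effects of traveling/multi-phase
  motion;
* on a motionless wall segment, lubrication theory gives
  `tau0 ~ 3 mu q_bar / (2 h0^2) > 0` on *both* flanks (the time-mean flux
  `q_bar` is station-independent), so the paperlike sign pattern requires
  the AVC flanks themselves to move, with the constriction's gap
  oscillation correlated with the through-flux oscillation.

The lubrication model used for design: with gap phasor `G = i m` and flux
phasor `Q(x) = Q0 + 2 pi integral m dx'` (continuity), imposing a periodic
pressure yields `Q0`, and
`tau0(x) ~ 4 (q_bar / g0^2 - Re[Q conj(G)] / g0^3)`.  The actual amplitude
and phase profiles of a live heart are not shipped with any dataset we can
consume; the preset is a configurable stand-in, not measured kinematics.

### Boundary-integral solver

Single layers of regularized Stokeslets on both walls (and on each RBC
membrane).  The x-periodicity is exact: the kernel is the closed-form
singly periodic 2D Stokeslet (derived by periodizing `log r` to
`log|sin(k z / 2)|`, `k = 2 pi / length`), with the nearest image replaced
by the regularized free-space Stokeslet of blob scale `eps`.  The
corresponding closed-form periodized stresslet evaluates wall traction.
Both kernels are validated against brute-force image sums in the tests.
No image-truncation parameter exists.

* Collocation is uniform in arc length along each wall (satisfying the
  uniform-spacing assumption even across the constriction shoulders), with
  recording interpolated back onto a fixed station grid.
* Regularization `eps = 0.5 * spacing` by default.  The dominant error of
  a regularized single layer is an O(eps) apparent wall displacement
  (~0.25 eps into the fluid); smaller eps improves traction accuracy but
  increases the interpolation leak of no-slip between collocation points.
  0.5 is the compromise used for stress profiles; the flux-balance
  consistency check uses `eps = 1.0 * spacing`, where the leak is smallest.
  Both are config-exposed.
* Wall traction is evaluated from the stress field of all layers at the
  collocation points; evaluating a layer's stress on itself returns the
  two-sided average, so half the traction jump (the force density) is added
  to land on the fluid side.  Sign convention: positive shear = traction on
  the wall pointing toward +x (atrium -> ventricle).  Normal traction is
  recorded alongside.
* The wall layers are closed curves in the periodic strip, so normal-
  oriented densities induce no flow; the minimum-norm least-squares solve
  fixes these null components without affecting the shear traction.
* The indeterminate mean pressure gradient of a periodic channel is an
  explicit degree of freedom: zero by default (pumping arises from wall
  motion only), or solved for under an imposed net flux (used by the
  plane-Poiseuille oracle).

Accuracy at the default oracle geometry (plane channel, 128 points/wall):
Couette and Poiseuille tractions within 1%.  In the curved tube the
remaining O(eps) bias is a smooth few-percent underestimate in the wide
chambers; the qualitative pattern quantities (argmax location, signs,
monotonicity) are insensitive to it.

### RBC membranes

Closed discrete curves (32 nodes) with linear stretching (`ks`, default 4)
and linearized bending on the turning-angle curvature (`kb`, default 0.005,
both nondimensional), zero spontaneous curvature, rest shape an ellipse of
aspect ratio 2 with semi-axes (0.2, 0.1) — equivalent radius ~0.4 of the
AVC half-width, matching the zebrafish RBC-to-lumen size ratio at these
stages.  The stretching stiffness is set high enough that the cells act as
stiff particles that measurably load the wall (soft membranes at desk
scale perturb the wall stress by less than the beat-to-beat fluctuation of
the phase average, which would make the cell-number dependence
unmeasurable in short runs); stiffness and shape sweeps are expressed in
these nondimensional ratios.  Forces are the exact analytic gradient of the discrete
energy (finite-difference validated; zero net force/torque to round-off).
No viscosity contrast (lambda = 1), which keeps the coupling single-layer.
A short-range quadratic repulsion (cutoff 0.05) regularizes near contacts
between cells and with the walls; the exact contact model is numerical
regularization, not physics.  Nodes are redistributed at equal arc length
every 20 steps with an exact area restoration (uniform rescale about the
centroid), so enclosed areas are conserved to the stated <1% over a run.

### Time integration

Heun predictor–corrector on the membrane nodes; each stage solves the
instantaneous wall problem with the current membrane force layers.  Default
desk-scale resolution: 128 points/wall, 200 steps/beat, 8 beats with the
first 2 discarded before statistics (phase averaging assumes statistical
periodicity).  Cells are seeded by rejection sampling, non-overlapping,
over the whole moving span (the narrow AVC rejects automatically); the seed
is recorded.  Identical configuration and seed reproduce records
bit-identically.  With no cells the flow is instantaneous, so only the
sampling instants are solved.

The test-suite and acceptance runs use reduced sizes chosen to preserve the
measured behavior: 96–128 points/wall, 100–120 steps/beat, 3–6 retained
beats, up to 20 cells.  The published-scale 106-cell case is a documented
scale-up of the same configuration, not a shipped fixture.

## Shear-stress decomposition

Phase average: samples are distributed to the two nearest of `bins`
(default 64) phase bins with linear weights; bin centers sit at phases
`b / bins`, so sampling grids commensurate with the bin grid are binned
without smearing.  Harmonics: FFT of the one-period curve, scaled so a pure
`A sin(2 pi k t / T + phi)` yields amplitude `A` and phase `phi`; `K = 3`
harmonics reported by default.  `tau'`: RMS of the deviation of the raw
series from the phase average evaluated at each sample's phase by periodic
linear interpolation.  The beat period is taken from the known wall-motion
period; an autocorrelation-based estimator is provided for measured
signals.  The variance identity
`mean(tau^2) = tau0^2 + 1/2 sum tau_k^2 + tau'^2` holds to 1e-6 for
band-limited signals with an integer number of beats and `K = bins/2 - 1`
(white noise deposits power in the Nyquist bin, which `K` excludes by
construction).

## Phantoms and unfolding

The phantom voxelizes a spline tube with elliptic cross-section: the shell
is a hard-edged annulus smoothed by a 1-voxel Gaussian (giving sub-voxel
edge localization something realistic but controlled); the photoconverted
label forms two rings flanking a gap whose arc length is exact ground
truth.  Band edges are defined on centerline arc length and swept around
the azimuth, with an optional per-azimuth sinusoidal edge offset.  Voxel
conventions: arrays (z, y, x), physical position = index * spacing,
half-open intervals, no half-voxel offset.  Output TIFFs are plain
(non-OME) with axes/spacing metadata so that pipeline manifests are
byte-reproducible; the OME UUID would break that.

What the phantom does *not* emulate: real myocardium texture, anisotropic
PSF blur, beating-motion artifacts, photobleaching, intensity
inhomogeneity.  Passing the recovery tests demonstrates the geometry
pipeline (centerline fit, frame transport, projection, edge localization),
not robustness to those confounds.

Unfolding: seeded centerline (>= 3 ordered lumen points), refined toward
local intensity centroids, smoothing spline, arc-length parameterization
(adaptive-quadrature cross-check at 0.1%), rotation-minimizing frames
(double reflection) with `theta = 0` anchored to a user-set anatomical
direction.  For each (s, theta), a ray from the axis locates the shell as
the structural-channel peak (parabolic sub-sample refinement); each channel
projects as its maximum within a band around that radius; rays leaving the
stack are flagged missing, never zeroed.

`L` is measured on the *nonphotoconverted* gap (the definition used for
the shortening factor), as arc length along `s` (the unfolded image is
arc-length-parameterized by construction): per column, smooth, binarize at
half of the band plateau, interpolate the two inner band edges.  A single
interior band means the labels merged (`L = 0`); a band touching the field
edge flags the column missing.  Quadrants are four contiguous half-open
90-degree sectors (superior/exterior/inferior/interior) centered at a
configurable anatomical offset.

## Group statistics

Unpaired two-sample Student's t-test, pooled variance, two-tailed,
per quadrant, `df = nA + nB - 2` (Welch behind a flag); no multiple-testing
correction across quadrants, stated in the output metadata.  The null
rejection rate at alpha = 0.05 is calibration-tested at 1e4 replicates.

## Numerical choices and edge cases

* Dense solves use column-pivoted QR least squares (`gelsy`); residuals are
  reported on the solution object.
* Degenerate membrane segments, self-intersecting curves, wall penetration
  and elastic-energy blow-up abort with diagnostics rather than continuing.
* Zero-variance t-test inputs: equal means give (t=0, p=1); unequal means
  give p=0 flagged by infinite t.
* A trailing partial beat is discarded (logged) before phase averaging.
* Ties in azimuth-to-quadrant assignment go to the next sector (half-open).

## Known limitations

* 2D only; no elastic wall mechanics; no inertia.  These match the regime
  the model is built for and are out of scope by design.
* The O(eps) wall bias of regularized single layers limits pointwise
  traction accuracy in the curved tube to a few percent at desk
  resolutions; pattern-level quantities converge much faster.
* The preset kinematics is a designed stand-in for unavailable measured
  profiles; quantitative stress values are therefore not comparable to any
  specific embryo, only the pattern structure is.
* RBC membranes use a minimal elastic model (no viscosity contrast, no
  thermal fluctuations, 2D); stiffness/shape sweeps are expressed in
  nondimensional ratios.
* At desk scale (<= 20 cells, a few retained beats) the suspension is
  dilute and the canal is cell-depleted for most of each beat (roughly one
  cell transits per six beats at 20 cells), so the cell-number dependence
  of the *periodic* stress amplitudes at a single AVC station sits inside
  the beat-to-beat fluctuation band of the phase-average estimator and its
  sign varies with the seeding realization.  The *nonperiodic* component
  tau' at the same station grows strongly and monotonically with cell
  count.  Resolving a clean linear trend of tau1 with cell count requires
  dense suspensions (order 100 cells) and long-run statistics, which this
  package treats as a documented scale-up rather than a default
  configuration.
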