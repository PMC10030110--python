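# Methods

This note records the models implemented in `terrarun`, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical conventions a user should know before
trusting a number.

## Coordinates, units, normalisation

World coordinates are x lateral, y longitudinal (along the track),
z up, in metres; forces in newtons; angles in radians. Back-and-forth
running is handled by expressing every fore-aft quantity in the
direction-of-travel frame (+ = forward for that traversal). Lengths
are additionally reported in %LL (percent of leg length ℓ) and speeds
in Froude units v/√(gℓ), with g = 9.81 m/s² and the mean-subject
ℓ = 0.89 m, body mass 66.1 kg, foot length 190 mm.

## Terrain representation and roughness statistics

Terrain is a node-registered rectangular height grid (default
resolution 5 mm) with a plain-text matrix + JSON sidecar format that
round-trips bit-exactly.

*Patch statistics.* The per-landing unevenness measure is the
interquartile range of heights (h_IQR) in an axis-aligned rear-foot
sized patch, 95 mm x 95 mm (half a 190 mm foot length per side). All
quantile computations in the package use the linearly interpolated
order-statistic rule (`numpy.percentile` default), everywhere and
consistently. Patches overhanging the track edge are clipped to the
gridded region and flagged rather than rejected.

*Amplitude and wavelength.* Track-level roughness is measured along
longitudinal transects (grid columns): each transect is smoothed with a
20 mm moving average, alternating local maxima/minima are detected
(consecutive same-type extrema are merged, keeping the more extreme
one), and each extremum is then refined to the raw-height extremum
within half a smoothing window so amplitudes are not attenuated by the
smoothing. Amplitude is the absolute height difference of consecutive
alternating extrema (peak-to-valley); wavelength is the separation of
consecutive peaks. The transect (1D) convention was chosen over 2D
neighbourhood extrema because the reported wavelength statistics are
along-track separations; it recovers (2A, λ) on a pure sinusoid to
within a grid spacing.

*Cell grid.* For footstep counting the analysed region is tiled into
half-open cells of 0.5 x 1.0 foot lengths (longer side along the
track), from the region's lower corner; a trailing sliver narrower
than a cell is not tiled.

## Synthetic terrain generator

The three track classes are flat, uneven I (target peak-to-valley
amplitude 18 mm, wavelength 102 mm) and uneven II (28 mm, 108 mm),
with the targets taken from the study conditions the package emulates.
A field is produced by band-pass filtering a seeded white-noise grid in
the Fourier domain (Gaussian annulus around the centre wavenumber,
relative bandwidth 0.4) and iteratively (i) rescaling heights and
(ii) retuning the centre wavelength until the extremum-based
measurement above reproduces the target means within 0.5 mm and 3 mm.
The same noise realisation is refiltered every iteration, so the field
is a pure function of (spec, seed). The iteration typically converges
in under ten passes; non-convergence raises an error carrying the
achieved statistics. The amplitude *spread* (SD) is an emergent
property of the bandwidth and is reported but not calibrated.

## Synthetic trials

`generate_trial` simulates back-and-forth shuttle running on a terrain
field and returns marker trajectories (300 Hz), a force-plate trace
(600 Hz, plate region at the track centre, 1.2 m long) and the exact
ground truth. Defaults are the mean-subject trial statistics: CoM
speed 3.2 m/s, step length 1.12 m (SD 0.053 m), step width 0.042 m
(SD 0.030 m), forward foot landing speed 0.37 Froude (SD
configurable), touchdown leg angle 0.20 rad, CoM vertical landing
speed 0.7 m/s downward (a nominal value, exposed as a knob), braking
impulse fraction 0.06, duty factor 0.28.

Deliberate idealisations, chosen so that recovery tests are sharp:

- a single *virtual* foot performs every step, alternating its lateral
  offset ±s_w/2 about the track centre line; its swing is a fast cubic
  transport followed by a constant-velocity landing approach (120 ms),
  so landing velocities are exactly recoverable by the 100 ms cubic
  pre-touchdown fit and detection timing errors do not leak into the
  landing speed;
- the heel stops instantaneously at touchdown and stays put through
  stance at the local terrain height plus the standing reference;
- the CoM is the mean of four pelvis markers, translates
  piecewise-linearly between touchdown anchors (so per-step speed is
  exactly step length over step duration) with a per-step cosine
  vertical excursion whose touchdown derivative equals the configured
  landing speed;
- the vertical ground reaction is a two-bump profile whose stance
  impulse equals body weight over one step period; the fore-aft
  component is a braking lobe with *exactly* the configured impulse
  fraction of the aerial forward momentum followed by an equal
  propulsive lobe.

None of this is a physiological simulation: swing-phase foot speeds
are unphysical (the virtual foot covers a full step per swing), there
is no double-peak timing variability, no soft-tissue dynamics and no
CoM sway by default. Passing recovery tests therefore demonstrates the
*analysis* pipeline's correctness, not realism of the generator; on
real data the detection thresholds (not the estimators) are the parts
that would need re-validation.

Respirometry is generated as breath-sampled VO2/VCO2 with an
exponential rise from standing rest to the running plateau
(configurable time constant, default 30 s), converted from target
metabolic powers via the Brockway-type equivalence below.

## Kinematics

*Alignment.* The horizontal CoM path's principal axis is rotated onto
the track's y axis; rotations beyond 5° are clamped with a warning
(they indicate a degenerate path, not instrument misalignment).

*Stance detection.* A stance is a contiguous interval where the heel
height is within 15 mm above its standing reference — the tolerance
that keeps stances detectable when the heel lands on a local terrain
peak — and the 10 Hz-low-passed heel forward speed attains a minimum.
Event timing is then refined on the *positional* plateau: the heel's
longitudinal position is constant during stance, so touchdown
(liftoff) is the first (last) sample within a noise-scaled tolerance
(max of 2 mm and 4 robust SDs) of the stance reference position.
Candidate events closer than 0.3 s to the previous touchdown are
rejected. On noise-free synthetic trials this recovers touchdowns and
liftoffs to within one frame (3.3 ms); with marker noise the errors
grow monotonically. Stances whose landing height exceeds the 15 mm
gate (possible on the roughest fields) are legitimately missed — the
same limitation the experimental criterion has — and steps at the
track-end turnarounds are excluded from analyses, mirroring a capture
volume that covers only the central portion of the track.

*Per-step measures.* Step length/duration/speed from consecutive
same-direction touchdowns of the CoM; step width as twice the nearest
approach of the stance heel to the total-least-squares line through
the stance-phase CoM path (horizontal plane); virtual leg = heel→CoM
segment at touchdown, its angle from vertical signed positive when the
heel is ahead of the CoM in the direction of travel; landing
velocities from least-squares cubics over the 100 ms before touchdown,
differentiated at the window end, for heel and CoM alike; retraction
rate ω = |v_rel ⊥ leg| / |leg|; meander per traversal as
(d − d0)/d0 with d the CoM path length and d0 the extent of its
projection onto the traversal's principal axis (hence meander ≥ 0).

## Kinetics

Force channels are filtered with a zero-phase Butterworth low-pass,
effective 8th order at 270 Hz: a 4th-order design run forward and
backward, the common biomechanics realisation — the forward-backward
pass squares the magnitude response, so the design's −3 dB point
becomes a gain of 0.5. (The alternative reading, an 8th-order design
applied twice for 16th-order magnitude, was rejected as nonstandard.)
Touchdown on the plate is the first crossing of baseline mean + 4
baseline SDs (population SD of the declared unloaded interval)
sustained for ≥ 5 ms; liftoff is the symmetric drop.

The fore-aft impulse J*_y is the magnitude of the maximal *braking*
(negative) excursion of the cumulative trapezoidal integral of the
direction-of-travel fore-aft force from touchdown; for canonical
braking-then-propulsion traces this coincides with the maximum
absolute cumulative integral, and a stance with no braking phase has
J*_y = 0. It is normalised by m·v_y with v_y the mean CoM forward
speed of the preceding flight phase (falling back, flagged, to the
touchdown CoM speed when no flight phase is found).

## Four-link collision models

The leg-plus-torso system is a planar chain: foot A–B (length one
foot length, inclined 20° heel-down at strike), shank B–C, thigh C–D
collinear with the virtual leg at the touchdown angle θ, torso D–N
vertical above the hip. The contact point O sits at the foot-strike
index s (default 0.15, rear-foot strike) along the foot from the heel.
Segment masses, lengths, centres of mass and radii of gyration come
from standard gait-analysis anthropometric tables (masses 0.0145,
0.0465, 0.100 of body mass for foot, shank, thigh, torso the
remainder; leg segment lengths 0.464ℓ and 0.462ℓ with ankle height
0.074ℓ, derived from stature fractions at ℓ = 0.53 stature; CoM
fractions 0.5/0.433/0.433/0.626 from the proximal end; gyration
fractions 0.475/0.302/0.323/0.496), shipped as an editable
`Anthropometry` config. When a touchdown (heel-to-CoM) leg length is
prescribed — 120 %LL for the mean subject — the leg segments are
scaled by the common factor (a closed-form quadratic root) that puts
the *composed* whole-body CoM at exactly that distance from the heel;
the factor is within a few percent of 1 for the default tables.

Pre-collision, the whole body translates with the CoM velocity and
rotates with a single angular velocity Ω⁻ — the leg retraction — set
so that the heel's forward speed matches the measured forward foot
speed. The collision is instantaneous, inelastic, point-contact: the
contact point comes to rest and only impulsive forces act.

*Rigid joints:* angular momentum about O is conserved,
M_b r_{G/O} × v_G⁻ + I_G Ω⁻ = (M_b |r_{G/O}|² + I_G) Ω⁺, and
v_G⁺ = Ω⁺ × r_{G/O}.

*Compliant joints:* each segment keeps its own post-collision angular
velocity; four angular-momentum balances (whole body about O, all
segments above the ankle about B, above the knee about C, torso about
D) are closed by the kinematic chain anchored at the resting contact
point and solved as a 4x4 linear system (residuals are checked to
1e-10 relative; singular geometry raises, naming the conditioning).

Both models output the impulse J = M_b (v_G⁺ − v_G⁻), its fore-aft
magnitude J*_y, and the normalised impulse J*_y / (M_b v_y⁻). Checked
invariants: zero contact-point velocity after impact, conservation of
angular momentum (rigid), first-degree homogeneity in the
pre-collision state, kinetic-energy dissipation, and rigid ≥ compliant
normalised impulse over the physiological input range.

*Angle-covariation convention.* Landing ensembles for the
impulse-versus-foot-speed regression covary the touchdown leg angle
with foot speed at magnitude 0.07 rad per Froude unit. The source
regression defines the leg angle without a signed direction, so the
sign with which that covariation couples into a signed-angle model is
a convention choice; this package applies it as
θ = 0.20 − 0.07·(fs − 0.4) — the coupling that *reduces* the braking
impulse at faster foot speed — because that is the only reading under
the heel-ahead-positive convention that is consistent with the
published model regression slopes (≈0.056 rigid, ≈0.020 compliant per
Froude unit); the opposite sign roughly doubles both slopes while
leaving their ratio unchanged. No anthropometric or geometric
parameter is affected by this choice.

## Foot-placement models

The blind scheme samples patch centres uniformly over the region where
a full patch fits. The directed walk follows the open-loop /
minimisation / noise stages described in the README; numerically:

- candidate patch evaluation snaps to a precomputed table of patch
  median/IQR at every node-centred position (exact order statistics,
  identical to `patch_stats` there); the 5 mm grid is far below any
  terrain feature, so snapping is immaterial;
- the search grid has inclusive endpoints, 21 x 21 candidates; a grid
  reaching beyond the valid region is clamped and flagged;
- minimisation ties are broken by distance to the open-loop target
  (so a uniformly level search region leaves the open-loop stride
  untouched — on flat ground the noise-free walk is exactly periodic),
  then lexicographically by (y, x); the walk is fully deterministic
  per seed;
- the von Mises noise angle φ ∈ (−π, π] is mapped as η = φ·σ/(2π), so
  the support (base) width equals σ and |η| ≤ σ/2;
- when the open-loop target leaves the straight section, the x
  position resets to the track centre and the direction toggles
  *before* the minimisation stage;
- step parity starts at i = 0 (first lateral offset +s_w), and noise
  is applied on flat terrain too (both choices are inconsequential
  for the reported statistics and are fixed for reproducibility).

Realized step lengths/widths are |Δy| and |Δx| of consecutive
same-direction footsteps. Note a property of the rectified width
statistic: the mean of |s_w + δ| exceeds s_w for any mean-zero lateral
perturbation δ, by about 4 % at the default s_w = 0.042 m and the
~0.027 m combined minimisation + noise spread. The realized mean step
*length* is free of this folding (s_l far exceeds the spread) and
matches the open-loop parameter within 1 %.

The foot-placement index normaliser S for a cell averages the window
counts only over step-length windows fully contained in the analysed
region; rows with no containing window, or S = 0, are flagged
undefined rather than extrapolated.

## Energetics

Metabolic power is P = a·V̇O2 + b·V̇CO2 with the Brockway-type
constants a = 16.58 kJ/L and b = 4.51 kJ/L (the citation-standard
values; overridable). The net rate discards the first 60 s of
standing and the first 180 s of running, averages the rest, subtracts,
and normalises by body mass. Steady state is asserted by a terminal
slope test — |linear trend of the final 2 min| below 1 % of the
segment mean per minute — replacing visual inspection; a non-plateau
trace is returned flagged, never silently.

## Pipeline and reproducibility

`run_pipeline` executes terrain → trial → kinematics → kinetics →
collision predictions → stepping schemes → placement index →
energetics, writing tidy CSVs and a JSON report with the config hash
and the per-stage seeds spawned deterministically from the single
global seed (`numpy.random.SeedSequence`). Identical (config, seed)
runs are byte-identical. The acceptance script uses the trial-level
problem sizes the package treats as its standard benchmark: a
21.6 m x 0.6 m field at 5 mm resolution, 1000-state landing ensembles
and 100,000-step walks.

## Known limitations

- The collision models are sagittal-plane and instantaneous; they
  cannot represent finite joint stiffness (only the two extremes),
  elastic restitution, or 3D effects.
- Terrain synthesis is a band-passed Gaussian field; real fabricated
  terrain has hand-made contours whose higher-order statistics
  (skewness, anisotropy) are not matched — only the amplitude and
  wavelength means are calibrated.
- The single-virtual-foot trial model cannot produce bilateral
  asymmetries, and its step-width ground truth presumes a straight
  CoM line (lateral CoM sway is off by default).
- Stance detection inherits the 15 mm height-gate limitation: landings
  on terrain peaks higher than the gate are missed by design.
- Mixed-model statistics on the emitted tables (terrain effects,
  index-vs-unevenness regressions) are intentionally out of scope; the
  pipeline exports tidy per-step and per-cell tables for external
  statistical software instead.
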