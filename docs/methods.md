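# Methods

This note documents the models, the numerical choices, and what the
synthetic experiments can and cannot show.

## Skeleton model and kinematics

A skeleton is 20 named joints in a right-handed camera frame (metres,
y roughly up), connected by a 19-edge bone tree. Clips are nominally 3 s at
30 Hz but any length ≥ 2 frames is accepted. Untracked joints are
forward-filled from the most recent tracked frame *within the clip* — never
across clips and never backwards, mirroring on-line operation; tracked flags
are preserved so gating still sees the occlusion.

**Body centroid.** The centre of mass of the 19 bones under a uniform-rod
assumption: bone midpoints weighted by bone length. This is the literal
centre of mass of a wire-frame body; an unweighted midpoint average is
available via `weighted=False`. When every bone has zero length (all joints
coincident) the centroid degrades to the plain midpoint mean, which equals
the common point. Bones with an untracked endpoint are dropped and the
centroid is computed over the remainder (a partial estimate).

**Body height.** The summed head-to-foot chain
HEAD–SHOULDER_CENTER–SPINE–HIP_CENTER plus the left/right average of
HIP_CENTER–HIP–KNEE–ANKLE–FOOT. The leg average makes H robust to a single
noisy leg and makes the chain a connected head-to-ground path, which is the
quantity the head-altitude module needs. H is rigid-motion invariant and
homogeneous of degree 1 in scale.

**Spine vector.** SHOULDER_CENTER − HIP_CENTER. A zero vector (degenerate
pose) disables the lean computation for that frame rather than producing an
arbitrary angle.

## Floor geometry

The floor plane is fitted by RANSAC: 500 random 3-point hypotheses, inlier
tolerance 2 cm on perpendicular distance, followed by a total-least-squares
(smallest principal axis) refit of the winning consensus set. The RNG is
seeded — identical inputs give identical planes. Coefficients are normalised
to a unit normal with B ≥ 0 so the normal points toward camera-up, which
makes `tilt_cos` (the cosine against the camera vertical (0,1,0)) exactly B.

**Altitude convention.** The module altitude is `|n·p + D| · cos θ_k` — the
perpendicular distance additionally scaled by the plane's tilt cosine. For
a level camera the factor is 1 and both readings agree; on tilted floors
the scaled reading is what the altitude modules consume, and
`strict=False` exposes the plain perpendicular distance for users who want
the purely geometric altitude. Both behaviors are shipped; the scaled form
is the default.

**In-plane basis.** Ground projection reports 2D coordinates in a
deterministic orthonormal basis: u is the unit projection of the camera
x-axis into the plane (z-axis fallback if degenerate) and v = u × n, so a
horizontal floor yields (u, v) = (x, z). Distances are basis-independent;
only the sign of the v coordinate depends on this choice.

**Base of support.** The perpendicular distance from the projected centroid
to the line through the two projected foot points. When the feet coincide
within 1 cm the line is numerically unstable and the measure degrades to
the point-to-point distance, which is the correct limit.

## Posture classifiers

Three binary soft-margin SVMs (push-up climb, pull-up climb, sitting) over
the z-scored 60-dimensional joint-coordinate vector with the inhomogeneous
quadratic kernel K(x, x′) = (x·x′ + 1)². Training is delegated to libsvm
(through scikit-learn); the fitted dual form — support vectors, signed dual
coefficients, bias — is extracted into a plain serialisable object and the
decision function is evaluated by our own kernel code, so saved models are
self-contained JSON.

The confidence measure is the raw decision-function value d (the
unnormalised functional margin), not d/‖w‖: the kernelised ‖w‖ would add
cost without benefit because the module's α absorbs any fixed scale during
calibration. The soft-margin penalty defaults to C = 1 and is exposed.

Backward feature elimination is a greedy wrapper: evaluate 5-fold
stratified-CV accuracy with each single remaining feature removed, commit
the removal with the best *strict* improvement (ties to the lowest feature
index), stop when nothing improves. By construction the final CV accuracy
is never below the initial one. It is deterministic given the seed.

## Risk modules

Every module maps its stimulus through p = 1 − exp(−d²/α). Conventions:

- **run** — the centroid is ground-projected *before* differencing, so
  vertical motion never leaks into the speed; velocities are finite
  differences (centred, one-sided at the edges) times the frame rate,
  smoothed by a 5-frame centred moving average. 5 frames (0.17 s) removes
  frame-to-frame tracking jitter without masking a sprint.
- **jump** — variance of the centroid's altitude over a trailing 30-frame
  (1 s) window; a 1 s window spans at least one full jump cycle at toddler
  jump cadences. Early frames use the available prefix; clips shorter than
  the window are evaluated whole.
- **sway / foot altitude** — gated to zero on frames where a sitting
  posture is detected (per-frame detection; a clip is partially gated if
  only some frames are seated) and on frames with untracked feet.
- **lean** — θ_h measured against the floor normal (0 = upright), in
  radians; invariant to spine-vector magnitude.
- **head altitude** — engaged only on frames whose feet are occluded; the
  stimulus is altitude(HEAD) − H clamped at zero, so a crouch never alarms.
- Clip-level risks are temporal means of the per-frame risks; disabled or
  failed modules contribute exactly zero, which is also how they enter
  fusion.

The shipped reference preset of α values (0.167, 0.168, 0.009, 0.017,
0.008, 0.115, 0.217, 0.214) reproduces a published sensor deployment whose
stimulus units are not fully recoverable; in particular the motion scales
(e.g. α_run = 0.009 (m/s)²) saturate at walking speed in SI units. The
preset is therefore a reference point only — **local calibration is the
normative source of α**, and all end-to-end experiments here calibrate.

## Calibration

Linearising the sigmoid gives a one-parameter least-squares problem with the
closed form α = Σaᵢbᵢ / Σaᵢ², aᵢ = −ln(1 − pᵢ), bᵢ = dᵢ². Rows with
pᵢ = 0 vanish from both sums; pᵢ ≥ 1 is rejected (log singularity). The
reported fit error is the mean absolute deviation of the refitted sigmoid
from the labels.

For clip-level calibration the regressed stimulus is the *temporal mean of
the raw per-frame stimulus* (speed, windowed standard deviation, distance,
angle, positive part of the SVM distance), not the mean of the risk:
averaging d keeps the linearised system exact and makes α transform
correctly (scaling all d by c scales α by c²). Averaging the risk instead
would make the fit nonlinear in α for no gain. Because clip risks are means
of per-frame risks while calibration sees mean stimuli, a waveform-dependent
(Jensen) offset of a few percent can appear between the fitted sigmoid and
clip-level risks for strongly oscillating stimuli; it is systematic,
monotone, and far smaller than the label quantisation step.

## Fusion and alarm

The rank-weighted mean uses weights wᵢ = (β^{i−1} − β^i)/(1 − β^n) on the
descending-sorted risks; the weights sum to one for every β ∈ [0, 1), β = 0
gives the maximum, β = 0.5 the halving weights (1/2, 1/4, …)/(1 − 2⁻⁸) and
β → 1 the arithmetic mean. β is fitted by a deterministic recursive grid
search on mean absolute error: coarse step 0.01 over [0, 0.99], then two
refinements at a tenth of the step around the incumbent. The alarm is the
strict inequality p_overall > T with T = 0.5 by default; a tie does not
alarm.

The SVM fusion thresholds the expert label at T to form classes, then
searches the standard power-of-two lattice C ∈ 2⁻⁵…2¹⁵, γ ∈ 2⁻¹⁵…2³ in
steps of 2², refined once at step 2^0.5 around the incumbent, selecting on
stratified k-fold CV accuracy (k = 5, capped by class counts; ties resolve
to the first point scanned, so the search is deterministic given the seed).

## Occlusion handling

The depth-profile summary carries per-frame mean depths of the upper- and
lower-body regions split at hip height. A frame is suspect when the lower
region reads more than δ = 0.3 m closer than the upper region (an occluder
in front of the legs) or is missing entirely. The mode flips to seated at
frame t when the previous `hold` = 3 frames were all suspect, and back when
the previous 3 were all clear — so isolated one-frame dips never switch the
mode and mode segments last at least `hold` frames. Seated mode disables
sway and foot altitude, exactly like a detected sitting posture.

## The synthetic generator

The generator is the package's study-condition definition, not a
convenience fixture. A ~0.84 m toddler template is animated by a small set
of drivers: gait translation with antiphase limb swing (walking ≤ 1.2 m/s,
running ≤ 2.5 m/s), whole-body vertical oscillation (rope-skipping ≤ 0.12 m,
high jumping ≤ 0.35 m amplitude), anterior-posterior torso sway relative to
the feet (dancing ≤ 0.15 m, tumbling ≤ 0.4 m), spine lean about the hips
(≤ 60°), static push-up/pull-up climbing poses with an ascent ramp (≤ 0.3 m)
and whole-body elevation (furniture, ≤ 0.6 m) — plus 2 mm isotropic joint
jitter, a random placement in the camera frustum per clip, and seeded
determinism throughout. Intensity ∈ [0, 1] scales each behavior's dominant
driver monotonically.

**The expert stand-in.** Ground-truth risk labels come from an explicit
deterministic rule: a saturating-exponential response of the behavior's
dominant *nominal* driver, quantised to the 0.1 questionnaire grid and
capped at 0.9 for single behaviors. The response scales were chosen once so
that the five safe behaviors sit below 0.5 and the five fall-prone ones
above at default intensity, matching how a childcare expert separates the
behavior classes. Combined behaviors take the larger component label plus
0.1, capped at 1.0. Because the labels are (quantised) sigmoids of the same
drivers the modules measure, the calibration chain is self-consistent: any
module whose measured stimulus is proportional to its nominal driver
recovers the label curve exactly up to quantisation. That is deliberate —
it makes the end-to-end benchmark a test of the *pipeline* (geometry,
classifiers, calibration, fusion), not of inter-rater noise.

**What passing does not show.** Real expert labels are noisy,
inconsistent between raters, and not a function of any single kinematic
driver; real skeletons have correlated, pose-dependent tracking errors,
and real homes contain clutter, multiple children and moving furniture.
The near-perfect synthetic benchmark accuracies therefore bound the
pipeline's algorithmic losses, not its field performance. The published
deployment this package re-implements reported ~92% on real recordings;
degradation of that order should be expected whenever the labeller and the
sensor stop being ideal.

## Experiment sizes

The reference experiment uses a 400-point floor cloud (20% outliers, 5 mm
noise), 90 + 90 training frames per posture SVM, 20 calibration clips per
module, and a 200-clip corpus (100 train / 100 test, stratified 50/50 by
alarm class, 15% combined behaviors). These sizes match the corpus scale of
the original deployment and run in a few seconds; growing them changes
nothing qualitatively.

## Known limitations

- The generator's kinematics are stylised (sinusoidal gait, rigid torso
  pitch); it emulates signal *scales*, not biomechanics.
- The reference α preset cannot be used with SI-unit stimuli for the motion
  modules (see above); calibrate locally.
- Occlusion handling trusts the depth-profile summary; there is no raster
  depth-image path because the generator never produces raster depth.
- Single skeleton per clip; interactions between children are out of scope.
- The published contingency tables are consumed as printed integers; their
  row/column orientation is fixed by the 50/50 test design (rows =
  decision), which also reproduces the published TPR/FPR.
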