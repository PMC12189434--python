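# Methods

This note documents the models, the synthetic data, the numerical
choices and the limits of what the tests demonstrate.

## 1. The estimation task

A *stance sample* is one support phase of walking, heel strike (0 %) to
toe-off (100 %). Inputs are the 3-D trajectories of 21 full-body
landmarks (head, C7, pelvis center, and bilateral shoulder / elbow /
wrist / hand / hip / knee / ankle / heel / toe), resampled to 100 time
points per coordinate — a 3 × 21 × 100 tensor in millimetres. Outputs
are single kinetic curves over the same 100 points: GRFx/GRFy/GRFz in
body weights (BW = m·g, g = 9.81 m/s²) and COPx/COPy in millimetres.
Axes are x = medial–lateral, y = anterior–posterior, z = vertical.

Two frame conventions remove nuisance information the models should not
exploit:

* **Kinematic reference** — the pelvis position at heel strike is
  subtracted from all marker coordinates of the sample, so absolute
  walkway position (and hence which force plate was hit) cannot leak
  into the input.
* **COP reference** — COP is expressed relative to the stance-side heel
  marker at heel strike, making curves comparable across plates and
  subjects. Consequently COPy starts near zero (about 5 % of foot
  length, the generator's initial contact point just anterior of the
  heel marker) and ends near the toe.

## 2. Synthetic gait generator

The generator stands in for a laboratory dataset: a walkway with three
force plates crossed in a right–left–right stepping pattern, markers at
100 Hz, plates at 1000 Hz.

**Population.** Subjects are drawn per sex from normal distributions
typical of a young-adult college population — males: age 20.3 ± 1.2 y,
height 1.77 ± 0.06 m, mass 71.8 ± 9.5 kg; females: age 19.8 ± 1.4 y,
height 1.64 ± 0.06 m, mass 56.0 ± 8.1 kg — with height and mass
truncated at ±3 SD. Walking speed is uniform on [1.1, 1.5] m/s
(self-selected comfortable range). Segment dimensions scale with height
(foot 0.152·h, leg 0.530·h, standard anthropometric ratios).

**Kinetics by construction.** A smooth center-of-mass (CoM) trajectory
is prescribed: constant mean forward speed with a sinusoidal speed
fluctuation (two cycles per stride, peak acceleration 0.18 g → braking /
propulsion), a vertical oscillation of 0.02·h peak-to-peak (two cycles
per stride; highest at mid-single-support, so the vertical force shows
the physiological double hump), and a ±20 mm lateral sway toward the
stance foot (one cycle per stride). Total ground force is then
F = m(a_CoM + g ẑ), apportioned to the feet by linear load-sharing
ramps over the first and last 15 % of each stance.

The stance occupies 0.5/0.85 ≈ 58.8 % of the gait cycle. This specific
value makes the double-support duration exactly equal to the 15 % ramp
length, so the two feet's ramps sum to one and the recorded plate forces
add up to m(a + g) identically — vertical GRF is zero exactly at heel
strike and toe-off, the per-foot peak stays in 1.0–1.3 BW for the whole
sampled population (verified analytically from the oscillation
amplitude and cycle-time bounds), and the vertical impulse over one full
cycle equals BW × cycle time by construction.

Cycle time is drawn per subject from N(1.15, 0.04) s truncated to
[1.05, 1.25] s with ±1 % per-trial jitter. It is sampled rather than
derived from speed and stature because short cycle times (< 1 s) would
push the prescribed oscillation's peak force beyond 1.3 BW.

**COP.** COPy advances from 5 % to 90 % of foot length via a smoothstep;
COPx is an S-curve of ±8 mm about the foot line (lateral at heel
contact, medial at push-off, mirrored between sides). COP is reported
only while the plate is loaded above the 20 N contact threshold.

**Markers.** The 21 landmarks ride on a scaled kinematic chain driven by
the CoM and the footfall sequence: trunk and head follow the CoM with
damped sway, arms swing in anti-phase with the ipsilateral leg, stance
heel and toe stay fixed on the ground, and the swing foot travels to its
next footfall with a smoothstep in y and a half-sine lift. The chain is
geometric, not an articulated-joint model — adequate because the learning
task only requires that the (noise-free) markers determine the kinetics
deterministically, which they do: cycle timing, subject scale and CoM
motion are all visible in the marker set.

**Noise.** Independent Gaussian noise on markers (SD 3 mm, the order of
good markerless-capture landmark error) and forces (SD 0.005 BW);
configurable, zero for physics tests. Everything is reproducible from
`(subject.rng_seed, trial_seed)`.

## 3. Preprocessing

Stance events are detected from each plate's vertical force: the first
interval above 20 N sustained for ≥ 100 ms (standard force-plate
practice; threshold and debounce configurable). Detected events land
within a few milliseconds of the generator's ground truth. A cycle
yields exactly three segments in right–left–right order; violations
raise a segmentation error naming the missing phase.

Curves are time-normalized with cubic interpolating splines on a
uniform grid (kinematics from ~65 frames at 100 Hz, kinetics directly
from ~660 frames at 1000 Hz; no pre-filtering, as the generator noise is
white and small). The default boundary condition is not-a-knot — the
scipy default, which reproduces cubic polynomials exactly; a natural
(zero end-curvature) variant is available and is verified in the tests
against an independent tridiagonal solve. Edge frames whose COP is
undefined (plate below threshold) are filled from the nearest loaded
frame before resampling.

Train/test splitting is by whole subjects (n per sex configurable;
default 5 + 5). Each cycle contributes two right stances and one left;
by default only the first right stance of each cycle enters the test
set (`right_stance_policy = "first"`, also `"second"` or `"both"`), so
10 test subjects × 10 trials give the canonical 100 right-side test
samples.

## 4. Input encodings and target scaling

* **MLP** — the tensor is flattened row-major (coordinate, marker, time)
  to 6300 values. Because raw inputs are millimetre-scale (up to ~10³),
  the MLP standardizes each feature with train-partition mean/SD stored
  on the estimator; without this, SGD at practical rates diverges.
* **CNN** — each coordinate plane (21 × 100) is spline-interpolated on
  both axes to `side_px` × `side_px` (227 canonical), affinely mapped to
  0–255 from the *global per-coordinate min/max of the training set*
  (per-sample scaling would erase amplitude information that the force
  regression needs), rounded half-up, and stacked as (x, y, z) → (R, G,
  B). The marker order is frozen; permuting it changes the image.
* **Targets** — each component's training curves are affinely mapped to
  [0.05, 0.95] (min/max with a 5 % symmetric margin) to match the
  sigmoid output layer, and predictions are mapped back to BW or mm.
  Scalers, input statistics and channel ranges are fitted on the
  training partition only and serialized with each model.

## 5. Networks and training

The networks run on a small numpy engine written for this package
(dense, im2col convolution, max-pooling, ReLU/sigmoid, SGD and Adam,
RMSE and MSE losses) — deterministic given the seed, gradient-checked
against finite differences in the tests.

* **MLP**: 6300 → 100 → 100 → 100 → 100, ReLU hidden, sigmoid output;
  RMSE loss; plain SGD, default learning rate 0.01 (0.05 recommended for
  small datasets; both configurable). Float64.
* **CNN**: AlexNet topology. At 227 px: conv 96@11/4, 256@5, 384@3,
  384@3, 256@3 with 3×3/2 max-pools after conv 1, 2 and 5, then fc
  4096-4096-100. Below 128 px a quarter-width variant (24, 64, 96, 96,
  64; fc 1024-1024-100, conv1 7×7/2) keeps the 5-conv + 3-fc topology at
  desk scale. MSE loss; Adam, default 1e-4. Float32 (convolution
  dominates the compute; single precision is standard for CNN training
  and markedly faster).

Batch size 128; reference epoch count 1000. Weight initialization is
Glorot-uniform, seeded; shuffling is seeded; no validation split or
early stopping by default (both exposed as options). Two training runs
with the same seed agree to machine precision.

## 6. Evaluation

rRMSE (percent, RMSE over the mean of the two curves' ranges) and
Pearson r per held-out sample; aggregates are mean ± sample SD (n − 1).
The printed correlation formula in the source literature carries an
obvious typo in the denominator (ū₁ where ū₂ belongs); the standard
product-moment definition is implemented. Architectures are compared per
(component, side, metric) with two-sided paired-samples t-tests, paired
by sample; significance is strict (p < 0.05) and no multiple-testing
correction is applied across the 20 comparisons (matching common
practice in this literature; noted in the report footer).

## 7. Scaled study profiles and problem sizes

The full design (146 subjects × 10 trials, 1000 epochs, 227 px images)
is far larger than needed to exercise the pipeline. The package's
reference desk-scale profile — used by the test suite and
`scripts/acceptance.py` — simulates 40 subjects × 10 trials
(1200 stance samples), holds out 5 + 5 subjects (100 right-stance test
samples), and trains the MLP for 250 epochs and the CNN for 20 epochs at
64 px. These sizes were chosen once from training-loss convergence: the
MLP loss plateaus by ~200 epochs at this data size, and the CNN's Adam
loss reaches ~1e-4 well before epoch 20. At this scale the held-out
accuracy lands in the r > 0.9 / rRMSE < 15 % band for the vertical and
anterior–posterior forces with either architecture.

## 8. What the synthetic results do and do not show

Passing tests demonstrate that the pipeline is internally correct: the
generator's kinetics follow its kinematics deterministically, the
encodings preserve the information they claim to, the networks can
recover the kinematics→kinetics map for unseen (synthetic) subjects, and
the metrics and statistics are exact. They do **not** show that the
accuracy figures transfer to real gait: real kinetics contain
segment-wise inertial contributions, heel-rise and foot deformation,
inter-subject variability far beyond three anthropometric parameters,
and markerless-capture error that is structured rather than white. The
generator also omits pathological gait, treadmill walking, marker gaps
and pose-estimation failure modes (all declared non-goals).

## 9. Known limitations and open choices

* The 21-marker set and lab-frame conventions are declared by the
  generator, not inferred from any published marker list.
* The generator's double-support force shape is a linear ramp — smooth
  enough for the learning contract, but not a measured loading profile.
* The CNN's marker-axis interpolation treats marker index as a spatial
  dimension; this is a fixed embedding, meaningful only because the
  order is frozen.
* Right stances are twice as frequent as left in each cycle (the plate
  layout records two right contacts); training uses both, and the test
  set keeps the first by default.
* Paired t-statistics become unstable when two models are near-identical
  (near-zero difference variance); the degenerate case raises instead of
  reporting a meaningless t.
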