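# Methods

This note documents the models implemented in `gain`, the choices made
where the design was genuinely open, the synthetic data generator's
assumptions, and the limits of what the synthetic experiments demonstrate.

## Signal model and angle reconstruction

Recordings follow the HuGaDB conventions: int16 accelerometer and
gyroscope counts (±2 g at 16384 LSB/g; ±2000 °/s at 16.4 LSB/°/s), uint8
EMG, a nominal 56.35 Hz frame rate, and an integer activity label per
frame.  All channels are scaled to [−1, 1] before feature extraction —
inertial counts divided by 32768, EMG midpoint-centered via
(v − 127.5)/127.5 so the sign of fluctuations around the resting baseline
is preserved.

Segment angles are measured to the horizontal in the sagittal plane.  The
sensor frame has y along the segment, x perpendicular in the sagittal
plane, z mediolateral, so at rest tilt = arctan(a_y/√(a_x²+a_z²)).  The
start angle is taken from the accelerometer after a causal 100-sample
moving average, evaluated once the filter window has filled (wearers are
assumed near-static at the start of a recording); the trajectory is then
tracked by rectangular integration (cumulative sum × 1/fs) of the
*unfiltered* z-gyroscope rate.  We deliberately do not average the
gyroscope before integrating: a trailing mean commutes with the integral,
so filtering the rate is identical to low-pass filtering the angle itself,
and a 100-sample window (≈1.8 s) would erase most gait-band content at a
≈1 s cycle.  Smoothing the accelerometer, by contrast, suppresses motion
artefacts exactly where the gravity-tilt reading is used.  On noise-free
synthetic data this pipeline reconstructs the true thigh angle to well
under 1° over a two-minute recording; integration drift from gyroscope
bias is the dominant error on noisy data and is not otherwise corrected
(no magnetometer or zero-velocity updates — out of scope).

Windowed features are causal and zero-filled over their warm-up frames so
all feature kinds stay frame-aligned.  "STD" uses the population
(divide-by-n) convention throughout; the sample convention differs by a
constant factor that min-max scaling would absorb anyway.  The EMG
gradient ∂ε is the backward first difference.  All model features are
min-max scaled to [0, 1] with bounds fitted on the training split only and
persisted with each model; constant columns scale to zero.

## Gait inference

The LSTM regressor has one hidden layer of 50 units, four inputs (left and
right thigh angle and angular rate, in that order) and two tanh outputs
(left and right shank angle).  Targets are mapped to (−1, 1) by an
invertible linear map fitted on the training-split range widened by a 10%
margin — tanh cannot reach its endpoints, so without the margin the
extremes of the swing would be systematically clipped.  Training minimizes
mean squared error in the scaled space (matching the tanh output), while
all reported errors are in degrees.

Sequences are cut into non-overlapping 15-frame chunks with the recurrent
state reset at each chunk boundary; the trailing remainder of a sequence
is dropped.  Optimization is Adam (β₁ = 0.9, β₂ = 0.999) on mini-batches
of 64 chunks, learning rate 3·10⁻³, at most 300 epochs; the forward and
backward passes are written directly from the gate equations in numpy and
are verified in the tests against an independent equation-by-equation
oracle (10⁻¹² agreement) and against central-difference numerical
gradients.  When training data from several participants is available,
the last participant (in sorted id order) is held out for early stopping
with patience 25 and the best-validation weights are restored.  Runs are
bit-reproducible given the seed.  Prediction is strictly causal and
streaming: one output per frame, state carried across calls, and feeding a
sequence whole or frame-by-frame is exactly equivalent.

The gait model is trained and scored on walking, running, stair ascent and
descent, and standing frames; sitting and the stand-up/sit-down procedures
are excluded (the controller suppresses inference there, and activity
labels are otherwise not used in training).

## Recognition modules

Three context-window classifiers share the same scoring rule: the class
score of frame t is the sum of per-frame Gaussian-mixture log-densities
over the last K = 20 frames (uniform class priors; ties broken by class
order), computed in the log domain via log-sum-exp and Cholesky
factorization.  Component counts: stand-up module — intention 10, sitting
1; sit-down module — intention 5, two for the rest; posture module
(sitting / standing / moving) — one each.  Covariances are full matrices:
the feature spaces are only 2–4 dimensional, so full covariance costs
little and captures the strong correlation between left and right
channels.  EM fitting is delegated to scikit-learn's `GaussianMixture`
(k-means initialization, covariance regularization 10⁻⁶·I), run one
iteration at a time so the per-iteration log-likelihood trace is exposed;
convergence is declared when the gain drops below 10⁻⁴ or after 200
iterations.

**Decision threshold.**  The intention decision is a windowed
log-likelihood ratio of the intention class against the best competitor,
compared with a threshold calibrated on training subjects for a target
event-level precision of 0.99.  Event semantics: a true intention event is
detected if any positive decision falls within its span extended by a
trailing slack equal to the recognizer's lag (the 20-frame context window
plus the feature window — the score necessarily peaks after the span ends,
because only then does the window contain the whole burst); every maximal
positive run outside all extended spans is one false positive.  The
calibration sweep descends from the top of the score range while precision
holds, and returns the most conservative threshold achieving the best
recall seen.  Descending further would only loosen the rule: on continuous
score traces the naive "smallest threshold with precision ≥ target" is
degenerate, because at very low thresholds all decisions merge into runs
that touch every span and event precision trivially returns to 1 while the
recognizer fires constantly.  Frame-level precision/recall are available
as a secondary metric.

Each module is evaluated (and in deployment, executed) only within its
operating context, as the controller gates it: the stand-up module while
sitting, the sit-down module while standing or in locomotion.  This
matters because the EMG burst of one intention is statistically identical
to the other's; only posture context disambiguates them.

## Controller

Five states — sitting, standing_up, standing, moving, sitting_down — with
the edge set {sitting→standing_up→standing→sitting_down→sitting,
standing↔moving}.  There is no sitting↔moving edge: a walking user must
stop and stand before sitting down, and a sitting user must stand up
before walking.  Invalid requests are ignored and logged, never acted on.
Quantitative triggers the transition graph needs but the state machine
itself does not define: leg-swing onset (standing→moving) is |thigh rate|
> 20 °/s for ≥3 consecutive frames on either leg; stillness
(moving→standing) is both thigh rates < 5 °/s held for 1 s; the stand-up
and sit-down procedures complete after a configurable duration (default
≈1.5 s).  These defaults are package choices — the triggers are only
qualitative in the source literature.

## Synthetic data generator

The generator's role is to produce recordings with the statistical
structure the models exploit, with known ground truth.  Per locomotion
activity the thigh angle is a two-harmonic sinusoid in cycle phase, time-
warped so stance occupies 62% of the cycle; the left leg runs half a cycle
out of phase.  The shank angle is a subject-specific nonlinear lagged
function of the same cycle, φ = c₀ + a·Δ + b·Δ², Δ = θ(u − lag) − offset —
the simplest family that makes the (θ, φ) scatter a closed loop (shank
lags thigh) while remaining learnable.  Defaults (walking: 1.1 s cycle,
thigh 65° ± 17° with a 4° second harmonic; coupling c₀ = 40°, a = 1.3,
b = 0.015 /deg, lag = 0.08 cycles; analogous settings for running and
stairs) were chosen to put angle ranges and cadences in the band reported
for casual adult gait while keeping all angles inside (−90°, 90°), where
the gravity-tilt convention is single-valued.

Variability has two levels.  Across subjects, amplitudes, offsets, cycle
durations and coupling coefficients are drawn from normal distributions
around the defaults (≈5–6% relative SD) — this is what makes
leave-one-subject-out prediction genuinely imperfect, since a held-out
subject's coupling cannot be identified from thigh signals alone.  Within
a subject, each cycle adds a smooth shank perturbation with SD 0.8° in
stance and twice that in swing, implementing as a generator *assumption*
the observation that swing kinematics vary more across people and cycles
than stance kinematics; the harness's swing-vs-stance error ordering test
probes exactly this structure.

Sensors invert the feature pipeline: accelerometers carry the unit-gravity
projection of the segment angle plus white noise (0.02 g SD), gyroscopes
the backward-difference rate plus white noise (1 °/s), a constant bias
(0.01 °/s SD) and a slow random-walk drift, all quantized at the hardware
sensitivities.  These noise levels are deliberately pessimistic relative
to the MEMS parts they mimic.  EMG is uint8 baseline noise with
high-variance bursts spanning each 1 s intention window, which always
immediately precedes the corresponding stand-up/sit-down label block.
Label scripts are validated against the activity-transition graph.  One
global seed fans out through `numpy.random.SeedSequence` to per-subject
substreams.

What the generator does *not* model: motion (non-gravitational)
acceleration in the accelerometer channels, realistic EMG spectra or
crosstalk, turning, foot kinematics, treadmill effects, or label noise.
Consequently, passing the synthetic end-to-end suite shows the pipeline is
implemented correctly and learns the intended structure — it does not by
itself establish error levels on real recordings, where the angle
reconstruction faces motion artefacts and the EMG separability is far
poorer (real sit-down recall is known to suffer at high precision).

## Evaluation protocol

Leave-one-subject-out: one fold per participant, the model trained on all
others.  Aggregation conventions: the headline held-out error is the
unweighted mean of per-fold means; per-activity errors pool frames across
participants, and their activity-mean is the unweighted mean across
activities; transition errors pool |true − pred| over ±15 frames (≈half a
second) around each label change between gait activities, per ordered
pair, reporting only pairs observed.  Gait phases are segmented from the
shank angle by the sign of the smoothed slope — upward segments are swing,
downward stance, zero slope inherits the previous phase (stance at the
start), and runs shorter than 3 frames merge into their left neighbor.
Detection latency is (first positive frame − onset)/fs per recalled event;
missed events are counted separately and excluded from mean latency.  F1
is always recomputed from its own precision and recall, and degenerate
zero-denominator cases return 0 with an explicit flag.

Problem sizes used by the shipped experiments: six synthetic subjects,
≈105 s each (≈5,900 frames), two stand-up and two sit-down events per
subject; LOSO training on five subjects per fold with the sixth held out,
the last training subject reserved for early stopping.  These sizes give
stable error estimates (≈29,000 scored gait frames, 12 events per
intention kind) while keeping a full run in minutes on one CPU.

## Known limitations

- Integration drift is uncorrected; very long recordings at high gyro
  bias will degrade both inputs and training targets.
- The chunked training objective conditions on a zero initial state while
  streaming prediction carries state indefinitely; the mismatch is mild at
  15-frame chunks but real.
- The threshold calibration transfers across subjects only as well as the
  score scale does; per-wearer calibration would be needed in practice.
- Event-level metrics on continuous traces are sensitive to run/span
  bookkeeping; the slack and sweep conventions above are stated precisely
  so results are reproducible, but other conventions exist.
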