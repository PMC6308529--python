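# gain — gait inference and intention recognition for lower-limb prostheses

`gain` is a Python toolkit for controlling robotic lower-leg prostheses for
people with double trans-femoral (above-knee) amputation.  The residual
thighs still move; the package infers what the missing shanks should be
doing from thigh motion alone, recognizes the wearer's posture and
stand-up/sit-down intentions, and drives a controller state machine — all
with strictly causal, low-latency models suitable for embedded use.  It is
aimed at researchers in wearable-sensor biomechanics and prosthesis control
who work with multichannel IMU + EMG recordings.

## What it computes

**Shank-angle inference.**  Sagittal-plane segment angles (measured to the
horizontal) are reconstructed from each IMU: the start angle from the
gravity tilt θ_start = arctan(T_y / √(T_x² + T_z²)) of the accelerometer,
the trajectory by integrating the gyroscope rate, θ(t) = θ_start + ∫ω(t) dt.
A single-hidden-layer LSTM (50 units) maps the four-vector
v_t = (θ_L, θ_R, ω_L, ω_R) of both thighs to the angles (φ_L, φ_R) of both
shanks, one output per input frame:

    f_t = σ(W_f [v_t, h_{t−1}] + b_f)       c_t = f_t·c_{t−1} + i_t·c̃_t
    i_t = σ(W_i [v_t, h_{t−1}] + b_i)       h_t = o_t·tanh(c_t)
    c̃_t = tanh(W_g [v_t, h_{t−1}] + b_g)    y_t = tanh(W_y h_t + b_y)
    o_t = σ(W_o [v_t, h_{t−1}] + b_o)

trained by truncated backpropagation through 15-frame chunks against the
squared error in scaled angle space.

**Intention and posture recognition.**  Sitting still, the shanks carry no
information about wanting to stand; the wearer signals intent through thigh
muscle EMG.  Each recognition module scores the last K = 20 frames of its
feature stream under per-class Gaussian-mixture densities and picks

    ŝ_t = argmax_s ∏_{k} P(v_{t−k} | s),

with mixtures fitted by EM.  Features are the windowed standard deviation
of EMG gradients v_w(t) = STD_{i=0..w}{∂ε(t−i)} (w = 5 for stand-up, 10 for
sit-down) and the between-thigh accelerometer difference variability d_x,
d_z.  The intention decision threshold is calibrated on training subjects
for a target event precision of 0.99 — false sit-down alarms would drop a
standing user, so precision is bought at the expense of recall and latency.

**Controller.**  A five-state machine (sitting ↔ standing via
standing-up/sitting-down procedures; standing ↔ moving) gates both models:
no gait inference while sitting, stand-up only from sitting, sit-down only
from standing.

**Synthetic cohorts and evaluation.**  A generator produces HuGaDB-format
recordings with ground truth: per-activity periodic thigh cycles, a
subject-specific nonlinear lagged thigh→shank coupling, 62%/38%
stance/swing timing with larger swing-phase variability, IMU traces that
invert through the angle pipeline, and EMG intention bursts.  The
evaluation harness runs leave-one-subject-out (LOSO) cross-validation and
reports degree errors (overall, per activity, per gait phase, around
activity transitions), event-level precision/recall/F1 and detection
latency.

## Worked example

```python
from gain import SyntheticConfig, generate_cohort, run_loso_gait_evaluation

cohort = generate_cohort(SyntheticConfig(), n=6, seed=7)
report = run_loso_gait_evaluation(cohort, seed=1)
print(f"held-out shank MAE: {report.overall_mae:.2f} deg")
for activity, (mean, std) in sorted(report.per_activity.items()):
    print(f"  {activity:10s} {mean:5.2f} ± {std:.2f} deg")
```

prints (six synthetic subjects, default sensor noise):

```
held-out shank MAE: 3.06 deg
  going_down  3.72 ± 2.88 deg
  going_up    3.37 ± 1.83 deg
  running     3.56 ± 2.35 deg
  standing    1.67 ± 4.68 deg
  walking     3.19 ± 2.51 deg
```

i.e. a network trained on five subjects predicts an unseen subject's shank
angles to about three degrees on average, best while standing and hardest
on stair descent.  The same cohort yields held-out stand-up/sit-down event
precision of 1.00 at recall 0.92 with ≈0.5 s detection latency.

The command-line interface wraps the same functionality:

```sh
gain simulate --n 6 --seed 7 --out cohort/
gain train-gait --data cohort --seed 1 --out model.json
gain infer --model model.json --recording cohort/S01.tsv --out pred.tsv
gain evaluate --data cohort --seed 1 --out report.json
```

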