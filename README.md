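# sslrun

Structure-specific musculoskeletal load (SSL) estimation during running from
one or two body-worn inertial measurement units (IMUs).

Running loads the Achilles tendon, patellar tendon, and the ankle and knee
joints with several body weights (BW) of force on every step, and cumulative
overload of a specific structure drives running-related overuse injury. The
laboratory gold standard for quantifying these loads — optical motion
capture, an instrumented treadmill and musculoskeletal modelling — cannot
leave the lab. `sslrun` implements the alternative: estimate the
time-normalized stance-phase load curve of each structure, and the derived
per-step characteristics, directly from pelvis- and foot-mounted IMU streams
with recurrent neural networks.

The package is aimed at biomechanics and wearable-sensing researchers. It
covers the complete analysis chain:

- **`sslrun.synth`** — a synthetic treadmill-cohort generator with known
  ground truth. Stance-phase loads follow a piecewise raised-cosine template
  `SSL(u) = A · rc(u; τ)` (peak `A` in BW, time-to-peak fraction `τ`) whose
  parameters are deterministic functions of belt speed, subject mass and
  latent gait factors that also shape the IMU waveforms, so the IMU → SSL
  regression task is identifiable and every downstream stage is testable.
- **`sslrun.imu`** — angular velocity from quaternion streams via the exact
  increment log `ω(t) = (2/Δt) · log[q(t)⁻¹ q(t+Δt)]`, zero-phase 5th-order
  40 Hz Butterworth filtering, initial-contact / toe-off detection from the
  foot's vertical acceleration (+0.18 g and −0.25 g thresholds with windowed
  decrease/increase constraints and gradual toe-off threshold relaxation),
  and cross-correlation stream synchronization.
- **`sslrun.loads`** — 20 Hz filtering and BW normalization of the load
  signals, 50 N vGRF step segmentation, greedy matching of force-plate steps
  to acceleration-detected steps, exclusion rules (stance 0.15–0.5 s, step
  0.21–0.6 s, signal dropout, loads outside (0.5, 15] BW), 100-point time
  normalization, and the three characteristics: peak (BW), impulse (BW·s,
  rectangular integral over stance) and average loading rate (BW/s, mean
  slope over 20–80 % of IC-to-peak for the tendon/ankle loads, 10–40 % of
  IC-to-TO for the knee).
- **`sslrun.features`** — the tabular battery: six subject features plus 50
  (dual-IMU) or 26 (single-IMU) biomechanical features (stance/step
  duration; impulse, max, mean, RMS, sample entropy, skewness per
  acceleration channel; max and mean per angular-velocity channel).
- **`sslrun.models`** — five estimators implemented in NumPy (forward and
  backward passes, Adam with staircase decay, early stopping): a
  hybrid-LSTM (two bidirectional LSTM layers of 20 units over the 12×100 or
  6×100 time series, concatenated with the tabular features,
  batch-normalized, dropout 0.2, dense-20 ReLU, dropout 0.2, linear 100-unit
  output), a TS-LSTM (same without the tabular branch), an F-NN
  (tabular-only dense net), an L1-regularized linear baseline (strength
  tuned on validation loss over a log grid in [1e-4, 100]) and a mean
  regressor.
- **`sslrun.evaluate`** — subject-level 5-fold cross-validation with a
  nested 5/6–1/6 train/validation split, per-fold standardization, pooled
  MSE/MAPE/R² curve metrics, characteristic metrics derived from the
  predicted curves, Monte Carlo dropout uncertainty (repeated stochastic
  forward passes) and channel-ablation analysis.
- **`sslrun.pipeline` / `sslrun` CLI** — YAML-configured end-to-end runs
  with every intermediate table written as delimited text.

## Worked example

```python
from sslrun import evaluate

res = evaluate.run_recovery_experiment(seed=3, n_subjects=8,
                                       speeds=(2.22, 2.78, 3.33),
                                       steps_per_trial=20,
                                       structures=("achilles",),
                                       model_types=("ts_lstm", "mean"),
                                       max_epochs=100)
print("steps:", res.n_steps)
for key, m in res.metrics.items():
    print(key, {k: round(v, 3) for k, v in m.items()})
```

Output from this exact call:

```
steps: {'train': 285, 'val': 57, 'test': 114}
('ts_lstm', 'achilles') {'mse': 0.081, 'mape': 6.256, 'r2': 0.986}
('mean', 'achilles') {'mse': 0.729, 'mape': 19.012, 'r2': 0.87}
```

The generator produced 8 subjects × 3 speeds × 20 steps; after gait-event
matching and exclusion filtering, 285 steps from 5 subjects trained a
TS-LSTM for the Achilles tendon, 57 steps from one subject drove early
stopping, and 114 steps from 2 held-out subjects were scored. The TS-LSTM
explains 98.6 % of the pooled variance of the held-out Achilles load curves
(MSE 0.08 BW², MAPE 6 % on timestamps above 0.1 BW), while the
constant-prediction mean regressor reaches R² 0.87 — the recurrent model
recovers the speed-, mass- and gait-driven amplitude and timing variation
that a constant curve cannot.

A shell workflow over stored cohorts:

```bash
sslrun synth --n-subjects 10 --speeds 2.22,2.78,3.33 --seed 7 --out cohort/
sslrun events --in cohort/ --out events.csv
sslrun steps  --in cohort/ --out steps.csv
sslrun features --in cohort/ --sensors pelvis --out features.csv
```

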