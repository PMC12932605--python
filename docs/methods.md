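# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices and the known limitations of `sslrun`.

## Problem setting

The estimand is the stance-phase load curve of four musculoskeletal
structures — Achilles tendon force, patellar tendon force, ankle contact
force, knee contact force — expressed in body weights (BW) and
time-normalized to 100 samples per step, together with three derived
characteristics per step and structure:

- **peak** (BW): maximum of the curve;
- **impulse** (BW·s): rectangular sum of the 100 samples divided by the
  effective sampling rate `100 / stance_duration`;
- **average loading rate** (BW/s): `(SSL(p_up) − SSL(p_lo)) / (t_up − t_lo)`
  with the percentile frames rounded half-away-from-zero on the interval
  IC → peak (p = 20 %/80 %; Achilles, patellar, ankle) or IC → TO
  (p = 10 %/40 %; knee). The interval endpoints for predicted curves use the
  predicted curve's own peak frame; a peak in frame 0 makes the rate
  undefined and the step is excluded from that metric and counted.

Inputs are streams from two IMUs (pelvis, right foot; 3-axis free
acceleration in m/s² and unit quaternions at 240 Hz), the vertical ground
reaction force (vGRF, N, 1,200 Hz) for reference segmentation, and a
subject table (mass, sex, age, height, shoe length, sole thickness).

## Signal processing

**Angular velocity.** `ω(t) = (2/Δt)·log[q(t)⁻¹ q(t+Δt)]` with the
increment quaternion sign-canonicalized (scalar part ≥ 0) so the double
cover cannot inject half-turn artefacts, and the exact log map
(`angle = 2·atan2(‖v‖, w)`) rather than the first-order vector part; the
first-order form underestimates the rate by O(angle²), which matters at the
1e-6 rad/s tolerance our rotation-matrix oracle imposes. The series is a
forward difference: length T−1, timestamped at the left sample.

**Filtering.** Zero-phase (forward-backward) 5th-order Butterworth,
40 Hz cutoff for acceleration, 20 Hz for load signals. Zero-phase
application was chosen because event timing must not be lag-shifted; the
squared magnitude response this implies is accepted. Loads are then divided
by body weight `m·g` with `g = 9.81 m/s²`; filter-induced negatives above
−0.01 BW are clamped to zero.

**Gait events.** Initial contact (IC) is an upward crossing of +0.18 g of
the foot's vertical acceleration (in g-units); toe-off (TO) a downward
crossing of −0.25 g after the IC. Both must be embedded in the impact
morphology: within a 50 ms (12-sample) pre-window the signal must have
fallen by ≥ 0.1 g (window minimum preceded by a value at least 0.1 g
higher), and after an IC it must rise by ≥ 0.1 g within 8 samples. A strict
sample-by-sample monotonicity constraint is not implementable on zero-phase
filtered data — filtering smears the impact rise over several samples, so
the sample before the crossing is usually already rising — hence the
windowed net-excursion form. If no TO is found before the next IC
candidate the TO threshold is relaxed in +0.05 g increments up to −0.05 g;
ICs without a TO are dropped, and accepted ICs are separated by a 0.1 s
refractory interval. The same rule is implemented twice: vectorized in the
package and as a naive loop oracle in the tests.

**Synchronization.** Integer lag maximizing normalized cross-correlation,
ties broken toward zero. In the pipeline the correlation runs on smoothed
IC-indicator trains (GRF-derived vs. acceleration-derived) rather than raw
signals: the two modalities have different waveform shapes, so raw
cross-modal correlation peaks at a shape-dependent offset, while event
trains align at the true clock lag.

## Step construction and exclusion

Stance intervals are maximal half-open `[IC, TO)` regions where vGRF ≥ 50 N
(sub-10 ms regions discarded as chatter), 0-based at the GRF rate. GRF
steps are matched greedily one-to-one to acceleration-detected ICs within
50 ms; unmatched GRF steps are excluded. Step duration is **half the
ipsilateral IC-to-IC interval** — the contralateral step time under gait
symmetry. (Defining it as the full ipsilateral interval would be a stride,
0.66–0.77 s at these speeds, and the 0.21–0.6 s acceptance band would
reject every step; the half-interval definition is the only one consistent
with that band when only right-foot events are observed.) The final step of
a trial has no successor IC and is dropped as `incomplete`.

Exclusion rules run in a fixed order and the first failure is reported:
stance outside [0.15, 0.5] s → `stance_duration`; step outside
[0.21, 0.6] s → `step_duration`; ≥ 20 consecutive identical samples in any
raw acceleration channel → `corruption`; peak outside (0.5, 15] BW or any
value below −0.01 BW → `ssl_range`. The (0.5, 15] BW "expected range" is a
package default bracketing physiologic running loads with wide margins; it
is configurable. Dropout detection runs on raw (unfiltered) segments
because zero-phase filtering smears exact-zero runs.

## Synthetic cohort

The generator stands in for a laboratory data collection and defines the
study conditions for all tests.

- **Subjects.** Per-sex truncated normal anthropometrics (male: mass
  79.8 ± 9.5 kg, height 186.3 ± 7.4 cm, age 24.4 ± 6.7 yr, shoe
  31.0 ± 1.2 cm, sole 3.3 ± 0.8 cm; female: 63.2 ± 2.9 kg, 173.1 ± 5.9 cm,
  22.6 ± 3.5 yr, 28.4 ± 1.0 cm, 3.1 ± 1.2 cm), sex ratio 36:7 by default,
  truncation to physiologic ranges (mass 45–110 kg, height 150–210 cm) by
  redraw.
- **Gait timing.** Cadence 2.75 + 0.25·(v − 2.78) steps/s, ground-contact
  time 0.30 − 0.045·(v − 2.78) s with 3 % step-to-step jitter — cadence
  rises and contact time falls with speed, and both land mid-band of the
  acceptance windows.
- **Load template.** `SSL(u) = A · rc(u; τ)`, a piecewise raised cosine
  rising on `[0, τ]` and falling on `[τ, 1]`; mean exactly 1/2, so the true
  impulse is `A·stance/2` in closed form, which the pipeline's rectangular
  rule must reproduce within 2 %. Peak amplitude
  `A = base · clip(1 + 0.35·(v−2.78) + 0.20·(m−75)/10 + 0.15·(0.8 z_subj +
  0.6 z_step), 0.25, 1.6) · clip(1 + 0.05 ε, 0.85, 1.15)` with bases
  5.5/4.0/8.0/6.5 BW (Achilles/patellar/ankle/knee). Speed and mass carry
  most of the amplitude variance (a linear regression of true peak on speed
  and mass exceeds R² 0.5 on a default cohort) while the latent factors
  keep the mean-curve regressor clearly beatable. The clip bounds guarantee
  every clean peak stays inside the (0.5, 15] BW acceptance band. Timing:
  τ = τ₀ + 0.05·(v−2.78) + 0.04·z_τ, τ₀ = 0.47/0.38/0.46/0.42 — patellar
  load peaks earliest, mirroring where running loads culminate.
- **vGRF.** A ~0.12 BW contact offset plus an active raised-cosine peak
  (≈ 2.5 BW, growing with speed) and an early impact transient. The offset
  pins the 50 N crossings to the constructed stance window, making the
  measured stance, the stored true events and the analytic template window
  coincide — without it the 50 N crossings trim ~8 % of the template and
  the closed-form impulse oracle would be systematically biased.
- **IMU waveforms.** The foot's vertical channel scripts the detection
  morphology: a pre-contact dip to −0.45 g, a crossing of +0.18 g at the
  true IC rising to an impact peak of ≈ 2 g (scaled by the latent
  amplitude), a mid-stance plateau, and a push-off dip through −0.25 g at
  the true TO. The foot anterior-posterior channel and the foot angular
  velocity carry bells centred at the time-to-peak fraction; the pelvis
  oscillates at cadence with amplitude tied to the same latents. The shared
  latent factors therefore appear in both the inputs and the targets
  (coupling strength is a config knob), which is what makes the regression
  solvable. Orientations are built by integrating scripted single-axis
  angular velocities, so the quaternion-to-angular-velocity path can be
  verified against the script. Quaternions are renormalized after noise.
- **Acceleration convention.** The generator emits gravity-free
  acceleration in the sensor frame with channel index 2 vertical; the
  g-relative detection thresholds presuppose a signal oscillating around 0.
  Whether a real pipeline would subtract gravity first is a deployment
  choice the detection module does not make for the user.
- **Artifacts.** A configurable fraction of steps receives one of: a 25
  sample zeroed window in the foot vertical channel (`dropout`), a bridged
  300 N extension of the 50 N region past 0.5 s (`stance_inflation`), or an
  Achilles load rescaled to a 20 BW peak (`ssl_out_of_range`); truth labels
  are stored so the exclusion audit can assert reason-exact filtering.
- **Noise.** `noise_scale` multiplies all additive signal noise (0.03 g on
  acceleration, 5 N on vGRF, 0.03 BW on loads, 0.002 on quaternions) and
  only that; anthropometric variability has its own knob so a "low-noise"
  cohort keeps its between-subject structure.

What the generator does **not** emulate: soft-tissue artefact, sensor
drift and mounting variation, left-foot steps, double-support mechanics on
the force plate, surface/footwear effects, fatigue, and the broad waveform
diversity of real running. Passing tests therefore demonstrate that the
pipeline and models are implemented correctly and can recover a known
generative structure — not that the same accuracy holds on laboratory data.

## Models and training

All five estimators map a step to a 100-sample curve and share one predict
contract (non-negative-clipped curves). The neural models are implemented
directly in NumPy (dense, ReLU, inverted dropout, batch normalization, and
bidirectional LSTM layers with full backpropagation through time, in
float32):

- **hybrid-LSTM** — two bidirectional LSTM layers (20 units each) over the
  (100 × C) time series; the final hidden states of the second layer (40
  values) are concatenated with the tabular features, batch-normalized,
  passed through dropout 0.2 → dense 20 ReLU → dropout 0.2 → linear dense
  100. Returning final states (rather than full sequences) into the
  concatenation is a documented design choice, configurable in principle;
  batch normalization is applied to the concatenated vector.
- **TS-LSTM** — identical without the concatenation (time series only).
- **F-NN** — tabular only: dense 20 ReLU → dropout 0.2 → dense 20 ReLU →
  dropout 0.2 → linear dense 100.
- **linear L1** — multi-output linear map with an L1 coefficient penalty
  (subgradient, intercept unpenalized), trained with the same
  optimizer/early-stopping protocol; strength selected by validation MSE
  over the grid {1e-4, 1e-3, 1e-2, 1e-1, 1, 10, 100}.
- **mean regressor** — the pointwise mean training curve; no validation
  set.

Training protocol defaults (in `ModelSpec`): Adam, initial learning rate
1e-4 with staircase decay ×0.90 every 10,000 optimizer steps, MSE loss,
batch 64, ≤ 500 epochs, early stopping on validation MSE with patience 30
and best-epoch restoration. Targets stay in BW (inputs are standardized,
targets are not). The output layer's bias is initialized to the pointwise
mean training curve — a base-rate initialization that removes the many
epochs a zero-initialized output would spend learning the mean, and that
makes the L1 λ→∞ limit (intercept-only = mean curve) exact. Weight
initialization is Glorot-uniform with the forget-gate bias at 1;
reproducibility follows from the spec seed (single-threaded NumPy).

## Evaluation

Cross-validation partitions **subjects**, never steps: 5 folds, and within
each fold the non-test subjects split 5/6 train, 1/6 validation (at least
one subject). Disjointness is asserted at construction, not assumed.
Scalers (per tabular feature; per time-series channel pooled over training
timestamps) are fitted on training data only; zero-variance features are
centred, not divided.

Curve metrics are pooled over steps × 100 timestamps within a fold: MSE in
BW²; MAPE restricted to timestamps with true load ≥ 0.1 BW (near IC/TO the
truth approaches zero and an unfloored MAPE diverges; the floor is
configurable); R² = 1 − SSres/SStot about the pooled mean. Macro-averaging
is the unweighted mean over folds. Characteristic metrics (MSE, MAPE over
steps) derive the characteristics from predicted curves with the same
operations used for the truth.

**Monte Carlo dropout.** Dropout layers stay active at inference; 100
stochastic forward passes per step give a per-timestamp SD and, by deriving
peak/impulse/loading rate from each pass, per-characteristic SDs. SDs are
computed on pass-minus-first-pass residuals, which is mathematically
identical but returns exact zeros (not rounding noise) when dropout is
disabled. On the synthetic cohort the SD profile tracks the predicted load
(positive rank correlation): multiplicative dropout noise scales with the
activations that carry the load amplitude.

**Channel ablation** retrains a single-sensor TS model from scratch with
one of the six channels removed and reports the metric deltas; no weight
reuse.

## Desk-scale experiment sizes

The recovery experiment used by the tests and the acceptance script runs
10 subjects × 3 speeds × 30 steps at `noise_scale 0.3` with a single
subject-disjoint split (7 train / 1 validation / 2 test subjects, ≈ 870
accepted steps), learning rate 1e-3 and ≤ 120 epochs. The raised learning
rate is the package's scaled-conditions choice: this split yields ≈ 5·10³
optimizer steps versus ≈ 2·10⁵ at study scale, and Adam's parameter
displacement is bounded by (learning rate × steps), so the study-scale
1e-4 cannot traverse BW-scale targets in this budget. The smaller pipeline
audits (event detection, exclusion filtering) use 4–5 subjects × 2–3
speeds × 15–20 steps. The full 5-fold CV orchestrator is exercised on a
5-subject cohort with cheap models.

## Known limitations

- The LSTM implementation is CPU-bound NumPy; it is adequate for
  desk-scale cohorts, not for the ~30,000-step scale of a full study.
- The linear-L1 optimizer uses a subgradient of the penalty, so
  coefficients shrink toward but do not reach exact zeros (no proximal
  step); selection behaviour, not sparsity certificates, is what the
  baseline is for.
- Left-foot steps, marker-based side determination and the musculoskeletal
  modelling chain that produces real ground-truth loads are out of scope;
  the generator emits the four structure loads directly.
- Mixed-effects significance testing across models is out of scope; the
  evaluation reports effect sizes (metric differences) only.
- MAPE floors, the "expected range" exclusion bounds and the step-duration
  definition are documented package choices where the field has no single
  convention; all are configurable.
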