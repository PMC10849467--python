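# Methods

This note documents the models, procedures, and numerical choices behind
`imugrf`, in the order data flows through the package.

## Synthetic IMU generation (`imugrf.synth`)

Segment kinematics (position and orientation per time step) are turned into
accelerometer/gyroscope signals for eight body-worn sensors (trunk, pelvis,
both thighs, shanks, feet; z along the segment surface normal, x left,
y right-hand rule).

* **Filtering/resampling.** Positions and quaternion components are low-pass
  filtered with a zero-lag (forward–backward) 4th-order Butterworth filter,
  cutoff 15 Hz, then linearly resampled to 100 Hz. Quaternions are made
  hemisphere-continuous before component-wise filtering and re-normalized
  after interpolation; for the smooth, well-sampled orientations this
  pipeline handles, the difference from geodesic filtering is below the
  finite-difference error of the next stage.
* **Angular velocity.** The body-frame rate at step *t* is the rotation
  vector of `R(t−1)⁻¹R(t+1)` divided by 2Δt (second-order accurate and
  frame-correct; endpoints use their one-sided neighbor pair), converted to
  deg/s. Sensor frame rather than global frame, because that is what a real
  gyroscope measures.
* **Acceleration.** Central second difference of sensor position, plus the
  gravity vector `(0, 0, +9.81)` m/s², rotated into the sensor frame.
  Gravity is *added* so that a static, upright sensor reads +9.81 on its
  vertical axis — the reaction (specific) force a real accelerometer at
  rest reports. Endpoint samples copy their nearest interior value.
* **Mounting perturbations.** Each sensor is additionally rotated by three
  angles drawn uniformly in ±10°, composed intrinsically x→y→z about the
  sensor's own axes and applied on the segment→sensor mounting map
  (`M′ = P·M`). Reusing one motion trial under several perturbations
  emulates placement variability across recording sessions.

## Preprocessing (`imugrf.preprocessing`)

Continuous 100-Hz trials are cut into 128-sample windows (1.28 s) with 50%
overlap; the trailing remainder shorter than one hop is discarded. Two
exclusion filters follow, both with *strict* comparisons (a value exactly at
a threshold is retained, since the boundary behavior is otherwise
arbitrary):

* **Stillness**: a window is dropped when the mean over the 24 accelerometer
  axes of the per-axis standard deviation is below 0.2 m/s². A
  mean-acceleration criterion would remove nothing once gravity is in the
  signal, so the standard-deviation form is used for every corpus.
* **Outliers**: any sample with |acc| > 160 m/s² or |gyro| > 2000 deg/s
  (typical MEMS measurement ranges) drops the whole window.

Labeled gait trials are windowed from 40 samples before each annotated
stance onset (clamped at the trial start; windows overrunning the end are
dropped). Short drop-landing trials (80 steps = 0.8 s) are zero-padded to
128 samples and carry `valid_length` so padded rows are excluded from
statistics, losses, and metrics. Resampling of IMU/GRF trials is linear
interpolation onto the target grid, preserving duration to within one
output sample.

**Normalization** is per-axis z-scoring. Standard deviations below 1e-8 are
clamped to 1e-8 so constant axes map to exactly zero. Statistics are fitted
on training data only, over valid rows only. For *pre-training* the corpus
statistics are used. For *fine-tuning a pre-trained model* the IMU
statistics are carried over from pre-training while GRF statistics are
fitted on the labeled training fold: refitting the IMU statistics on a
small fold would shift the encoder's input distribution away from what it
was trained on and forfeit part of the transfer benefit (the acceptance
suite's pre-training contrast exercises this protocol end to end). The
random-init baseline fits everything on its training fold.

## Model (`imugrf.model`, `imugrf.nn`)

The window (128 × 48) is sliced into `128/L` contiguous time patches of
length `L ∈ {1, 2, 4, 8}`, each flattened to `L·48` values. During
pre-training, `round(r·n_patches)` patches (masking ratio `r`) are replaced
— in raw patch space, before embedding — by a single shared trainable mask
patch. Patches are linearly embedded to width `d`, a fixed sinusoidal
positional code (base 10000) is added (to masked positions too), and the
sequence passes through post-norm transformer encoder blocks
(multi-head self-attention → add & layer-norm → ReLU feedforward → add &
layer-norm), with dropout active only during training. Output heads are
per-patch linear maps: back to patch space for reconstruction, or to
`L × 3` values for GRF. Sensors absent at fine-tuning time are replaced by
one trainable substitution patch per sensor (shape `L × 6`, tiled across
time); per-sensor rather than per-sensor-per-patch keeps the parameter cost
negligible.

Published scale: `L = 1`, `d = 192`, 6 blocks, 8 heads, 512 feedforward
units, 10% dropout, layer-norm ε = 1e-5 → 2,096,544 trainable scalars
(≈ 2 M). Desk scale (`ModelConfig.tiny()`): `L = 4`, `d = 64`, 2 blocks,
4 heads, 128 feedforward units. Short patches are the published optimum
(the grid search favors `L ∈ {1, 2}` with 6.25–12.5% masking); `L = 4` is
the shortest patch whose token count keeps the full desk-scale experiments
fast on one CPU, and the default masking ratio stays at 12.5%.

Weight initialization: plain linear layers Kaiming-uniform, attention
projections Xavier-uniform, biases zero, layer-norm gain 1 / bias 0, mask
and substitution patches N(0, 0.02) (the data is z-scored, so small random
patches start near the data's scale without dominating it).

The network core is a compact reverse-mode autodiff engine on NumPy
(float64 throughout). At the problem sizes this package targets, runs are
bit-reproducible for a fixed seed on a single machine, which the test suite
relies on.

## Training (`imugrf.training`)

All objectives use AdamW (decoupled weight decay 0.01 on every parameter)
with a warmup–cosine schedule: linear ramp from `peak/warmup_steps` to
`peak` over the first 20% of steps, then cosine decay to ~0, no restarts,
no early stopping, no gradient clipping. Published budgets: pre-training
peak lr 1e-4, batch 64, 5×10⁴ steps; fine-tuning 300 steps at lr 1e-3
(head only, encoder frozen) then 300 steps at lr 1e-4 (entire model). The
head-first schedule prevents a randomly initialized head from distorting
the pre-trained representation.

Per pre-training step a fresh mask is drawn per window; batches are
shuffled without replacement per epoch and reshuffled each epoch; the loss
is the MSE over exactly the masked-patch entries (padded rows excluded).
The supervised transfer baselines (real IMU → GRF; synthetic IMU →
body-center acceleration) use the same encoder with a per-patch linear head
(3 outputs per time step) and full-window MSE, no masking. The fine-tuning
GRF head is always freshly initialized — the pre-training heads have
different output dimensions.

**Desk scaling.** The test and acceptance runs use the tiny architecture,
500 pre-training steps at batch 32, and a pre-training peak lr of 1e-3:
the published 1e-4 is calibrated to a 100× longer schedule and leaves the
encoder under-trained within a 500-step budget. Fine-tuning keeps the published 300 + 300
steps and learning rates at batch 32.

## Evaluation (`imugrf.evaluation`)

GRF is stored mass-normalized (N/kg), so "2% of body weight" is the
mass-free threshold 0.02 × 9.81 = 0.1962 N/kg; samples whose *gold* vGRF is
below it (swing/flight) are excluded, as are padded rows. Per participant,
all included samples are concatenated before computing Pearson ρ and RMSE
per axis (not averaged over windows). Peak-vGRF metrics pair the per-window
maxima of gold and estimate; rRMSE divides the peak RMSE by the
participant's global gold vGRF range (×100%). Windows with an empty phase
mask are skipped and logged.

Spectrum error is the one-sided FFT magnitude spectrum of the estimate
minus that of the gold signal, averaged across windows (signed by default;
absolute and complex-difference modes are selectable — the display
convention is genuinely ambiguous, and signed differences preserve the
direction of the bias). Cross-validation splits *participants* (never
windows) into k folds whose sizes differ by at most one. Scaling curves
subsample training *windows* with nesting (prefixes of one seeded
permutation), so smaller fractions are subsets of larger ones. Model
comparison is a one-way ANOVA across settings; only if p < 0.05 are all
pairwise paired t-tests run, with Bonferroni correction (p × number of
comparisons, capped at 1).

## Synthetic fixtures (`imugrf.fixtures`)

The generator emulates the *structure* of motion-capture + force-plate
datasets, not their biomechanics. An 8-segment rigid chain follows
periodic, participant-specific sagittal joint trajectories (harmonic
mixtures of the stride frequency, ≤ 6 Hz; cadence drawn from 100–130
steps/min; amplitudes, phases, and GRF gains vary per participant by ~15%).
Right-leg GRF is a smooth deterministic function of the same gait phase:
the vertical component is a double-peak stance profile
(`sin(πs) + 0.35·sin(3πs)`, normalized) peaking near 1.2 body weight and
exactly zero in swing; medial-lateral and anterior-posterior components are
smaller-amplitude functions of the same phase variable. Stance onsets are
the phase's swing→stance crossings. Drop landings are 80-step trials —
free fall from 30 cm, then a damped settling oscillation — whose vGRF is
derived from pelvis acceleration, so it is exactly zero in flight and
exactly consistent with the synthetic IMU signals. Sensor noise defaults to
0.05 m/s² (accel) and 0.2 deg/s (gyro), the magnitude of modern MEMS
sensor noise at rest; an optional stillness fraction freezes the trial
boundaries to exercise the stillness filter.

Because GRF and IMU are functions of a shared phase, the task is learnable
by construction (a ridge regression from flattened windows reaches ρ > 0.8
on held-out windows), so model-test failures indicate model defects, not
data defects. What the fixtures do *not* contain — soft-tissue artifact,
stride-to-stride variability, real inter-participant anatomy, non-gait
motions — means that passing tests demonstrate the pipeline's mechanics and
trainability, not real-world accuracy.

## Degenerate inputs and tie-breaks

Constant axes z-score to zero (ε-clamp); zero-variance inputs to Pearson ρ
and zero gold ranges in rRMSE raise errors rather than returning NaN; a
masking ratio whose patch count rounds to zero is a configuration error
(grid-search cells report it as invalid rather than aborting the grid);
window stores refuse to mix labeled and unlabeled windows; checkpoints
refuse to load under a mismatched architecture config.

## Known limitations

* The NumPy engine is single-device and optimized for clarity and exact
  reproducibility, not throughput; the published 5×10⁴-step, width-192
  configuration is out of desk-scale reach (the CLI exposes it, flagged as
  long-running).
* Gait events are taken from annotations; no event detector is included.
* No magnetometer channels, no C3D/BVH parsing, no soft-tissue or sensor
  bias simulation.
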