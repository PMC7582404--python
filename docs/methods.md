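# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the open design decisions behind `runfatigue`, in enough detail
to reproduce or criticise them.

## Problem setting

A runner wears tights instrumented with nine resistive textile strain
sensors (four hip, two knee, three ankle; one knee channel flagged noisy and
excluded from analysis) sampled at 100 Hz through a 40 kΩ voltage divider at
3.3 V. During an incremental treadmill test the runner reports a Borg RPE
score (integer, 6–20) every 180 s; speed starts at 8 km/h and rises 1 km/h
per report while the last report is below 13, then holds until the first
report ≥ 17, after which one more minute is recorded. The task is to
estimate the integer RPE of every stride (or 1-s window) from the strain
signals alone.

## Sensor model

The transduction is the standard strain-gauge relation, relative resistance
change proportional to strain:

    ΔR/R₀ = GF · ΔL/L₀,   GF = 5

followed by the divider, V = V_cc·R/(R + R_d) with R = R₀(1 + GF·ε),
R₀ = R_d = 40 kΩ, V_cc = 3.3 V. The linear working range is |ε| ≤ 0.30;
the simulator validates that every channel's waveform envelope stays inside
it for all Borg levels and raises otherwise. Gaussian readout noise
(default sd 0.005 V) is added after transduction and the readout is clipped
to [0, V_cc]. The excluded knee channel receives 20× the noise sd so the
default exclusion flag corresponds to something visible in the raw data.

## Synthetic session generator

The generator is the package's study stand-in; it emulates the protocol and
signal structure, not musculoskeletal physics.

**Exertion and protocol.** Each participant gets a latent monotone exertion
curve E(t) = E₀ + r·t with E₀ ~ U(9, 11) and r chosen so the rounded curve
first prints 17 at a time drawn uniformly from 29–37.5 min; reports are
round(E) at 180-s intervals, clipped to [6, 20]. Rounding a shallow line
naturally produces repeated scores (plateaus), as real participants show.
Sessions end 60 s after the first report ≥ 17, giving 30–40 minute sessions
within the 30–50 minute range typical of runs to voluntary exhaustion.

**Gait.** Each channel is a two-harmonic waveform in strain units,
ε(φ) = offset + amp·[sin(φ + φ₀) + h₂·sin(2(φ + φ₀))], advanced stride by
stride. Stride frequency is 1.35 Hz at 8 km/h with a shallow slope of
0.007 Hz per km/h — recreational runners absorb treadmill speed mostly with
stride length, so cadence rises only a few percent across the ramp. Cycle
periods carry multiplicative jitter with coefficient of variation
0.012 + 0.001·(RPE − 13).

**Fatigue drift.** Drift is linear in (RPE − 13), zero at 13 by
construction, and driven by the *reported* (piecewise-constant) score, so
the generator's ground truth coincides exactly with the labels a study
would collect. The default preset is hip-dominant: hip offsets drift by
−3.5 % and amplitudes by +0.875 % per RPE unit (−28 % and +7 % over the
8-unit span from RPE 9 to 17), mirroring the reported dominance of hip
kinematic changes in exhaustive running, where hip extension shrinks by
roughly a quarter while knee excursion barely changes. Knee and ankle
drifts are an order of magnitude smaller (≤ 0.2 % per unit), ankle slightly
larger than knee. Per-stride motor jitter — amplitude ×(1 + N(0, 0.015)),
offset + N(0, 0.001) strain per channel and stride — is the irreducible
noise floor: per-segment features cannot average it away, so channels whose
drift is below it stay uninformative. All randomness flows from one integer
seed through a single generator, making sessions bit-reproducible.

**What the generator does not emulate.** Real strain garments exhibit
textile–skin slip, posture-dependent offsets, step-to-step asymmetry,
non-stationary noise and participant-idiosyncratic fatigue signatures; the
generator's drifts are smooth, linear and identical across the session.
Passing the benchmark therefore shows that the pipeline recovers the
designed signal structure at realistic SNR — it does not certify accuracy
on real runners.

## Segmentation

Peaks of the reference channel (default `hip_1`) are local maxima with
prominence ≥ 0.3 of the robust (5th–95th percentile) signal range and
separation ≥ 0.4 s (cadences up to 150 strides/min per leg). Ties between
equal-height maxima within the minimum distance keep the earliest index.
Stride segments are consecutive peak pairs [pᵢ, pᵢ₊₁); window segments are
[p − w, p) with w ∈ {0.5, 1, 1.5, 2} s, default 1 s (the best-performing
length for this task). Windows that would cross the recording start are
dropped.

## Features

Per segment, channel and signal view (raw, first derivative): whole-segment
mean/min/max/ROM and mean/min/max of five contiguous near-equal
sub-segments (remainder samples to the earliest sub-segments), plus the
trailing-10-segment sample standard deviation (ddof 1, inclusive of the
current segment) of the four whole-segment statistics: 46 columns per
channel, plus one global stride-duration column (anchor-to-anchor time in
seconds — the garment measures no spatial stride length, so duration is the
temporal stand-in). The first derivative is computed on the full channel
signal (central differences, one-sided endpoints) and then windowed, so
segment edges introduce no differentiation artifacts. The first ten rows
are dropped rather than computed with a shrunken window, keeping every
retained row's features identically defined.

## Stacked model

Level 1 is a 100-tree random forest on the features; level 2 is a 100-tree
forest on a single column — level-1's held-out prediction — trained against
the same labels. Level-2's job is to snap level-1's interpolated estimates
onto the discrete levels the participant actually used. Design choices:

* **Held-out stacking signal.** Default is level-1's out-of-bag
  predictions: each row is predicted by the ~37 % of trees that did not see
  it, giving leakage-controlled stacking at zero extra cost. An internal
  K-fold variant (`stacking="oof"`, K = 5) and the naive in-sample variant
  (`stacking="naive"`) are provided.
* **Forest geometry.** `max_features="sqrt"` (randomized-subspace forest).
  At 369 columns the full-feature variant is ~8× slower per fit with no
  measurable accuracy gain on this task.
* **Voting.** Two passes of a 10-sample running median, centered with edge
  shrinkage (for the even window, one extra sample on the right); a causal
  `trailing` variant exists for streaming. A centered even-length median
  shifts a monotone ramp by up to half a step; on the near-piecewise-
  constant prediction series this only moves step edges by ≤ 1 sample. The
  filter is non-expansive, so smoothed values never leave the observed
  range.
* **Rounding.** Half away from zero (platform-independent), then clamping
  to [6, 20].

Determinism: level-1/level-2/fold seeds are all derived from the single fit
seed.

## Evaluation

R² = 1 − SS_res/SS_tot and RMSE are computed on the *final integer*
predictions, per fold, reported as mean (sd) across five folds.

* **Fold scheme.** Default `shuffled` draws RPE-stratified random folds
  (falling back to plain shuffled K-fold when a level has fewer rows than
  folds). Shuffled folds place temporal neighbours in train and test, so
  they measure within-session interpolation — the regime in which
  per-window scores near 1 are attainable. The `blocked` scheme holds out
  contiguous time blocks and is the honest extrapolation benchmark; its
  scores are substantially lower and it is the right choice for claims
  about unseen time periods.
* **Voting scope.** By default the out-of-fold level-2 predictions of all
  folds are reassembled into the session's temporal order and the median
  voting runs once over that full series before fold-wise scoring
  (`vote_scope="session"`). This matches the continuous-monitoring reading:
  every stride's final score is voted among its temporal neighbours,
  regardless of which fold predicted them. `vote_scope="fold"` restricts
  voting to contiguous runs inside each fold's own test set; with shuffled
  folds those runs are mostly singletons, so voting then does almost
  nothing and isolated off-by-one errors survive to the metrics.
* **Folds with constant test labels** have undefined R²; they are excluded
  from the R² aggregate with a warning (RMSE is always defined).
* **Importance and ablation.** Leave-one-sensor-out importance removes a
  channel's 46 columns, refits with the same seed (paired fold assignment)
  and reports (R²_without − R²_base)/R²_base; greater negative values mean
  greater importance. Joint ablation restricts the matrix to one joint's
  channels plus the stride-duration column.

## Benchmark and problem sizes

The replication benchmark simulates five participants (seeds 1–5 for base
seed 1), segments with 1-s windows (≈ 2 800–3 300 rows per participant),
and runs shuffled five-fold CV of the stacked model per participant plus
the three joint ablations; the whole run takes a few minutes on one CPU.
Unit and property tests use a fast exertion curve (RPE 11 → 17 in six
minutes, ≈ 560 windows) so the suite stays quick; the noise-robustness
property (non-increasing mean R² along a readout-noise grid of 0.002, 0.02,
0.1, 0.3 V, five seeds per level) uses those short sessions with three-fold
CV.

## Known limitations

* Labels are forward-filled from the most recent report, and the
  generator's drift switches at the same instants, so label noise at block
  boundaries is limited to windows that straddle a report — real RPE
  transitions are not instantaneous.
* The shuffled-fold scores characterise interpolation within a session;
  they say nothing about generalisation across participants or days, and
  the blocked scheme should be used for any such claim.
* The generator's hip-dominant preset builds in the expected ablation
  ordering (hip ≫ ankle > knee); the ablation machinery verifies recovery
  of that construction, not a biomechanical discovery.
* A constant-label session yields a degenerate but well-defined model (it
  predicts the constant); R² is undefined there and flagged rather than
  reported.
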