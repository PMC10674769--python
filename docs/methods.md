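# Methods

## The model of a fatiguing trial

The synthetic cohort is built around a single latent fatigue variable
per subject, `u(t) = borg(t)/10 ∈ [0, 1]`. The latent Borg ramp is a
monotone PCHIP curve through the milestones (0 → 0, 3 at 37% of the
subject's time-to-fatigue, 6 at 65%, 9 at 85%, 10 at 100%), floored
onto the CR10 response grid {0, 0.5, 1, …, 10}. Flooring (rather than
rounding) makes the reported 10 coincide exactly with the latent ramp
reaching 10 — the trial's stop rule — and produces the long plateau at
9 that subjects typically report before exhaustion. The milestone
placement makes the time spent in the three states roughly 37/28/35%,
matching the class balance such protocols produce. Ratings are queried
every `borg_query_interval` (default 20 s); the trial ends at the first
query answered 10, with `trial_duration_max` (600 s) as a safety cap.

All sensor streams are driven by `u(t)`:

* **Elbow angle**: `θ(t) = 70° − ROM(u)/2 · cos φ(t)` with
  `ROM(u) = rom_initial − rom_decay·u` (120° → 90° by default) and the
  cycle phase `φ` integrated from a period
  `P(u) = base_cycle_period·(1 + cycle_slowing_rate·u)` (3 s → 4.5 s).
  The fiber voltage is the inverse of the subject's two-point
  calibration plus 5 mV of white noise.
* **EMG** (1024 Hz): zero-mean noise shaped by overlap-added 2 s
  Hann-windowed band-pass blocks whose center frequency falls linearly
  with fatigue (90 Hz → 65 Hz, half-bandwidth 35 Hz), scaled so that
  the rectified-mean envelope tracks
  `(emg_amp_initial + emg_amp_slope·u)` %MVC (3% → 9%, the range
  observed for loaded biceps curls), modulated by a flexion-locked
  burst gain, plus a 2 µV sensor floor. The Gaussian rectified-mean
  identity E|x| = σ√(2/π) links the target %MVC to the carrier scale.
* **Wrist IMU** (128 Hz): gyroscope channels follow the angle
  derivative (deg/s), accelerometers the tangential acceleration of a
  0.30 m forearm lever plus gravity projections of the elbow angle;
  hence wrist kinematics slow and shrink as fatigue develops.
* **Neck IMU**: cycle-locked oscillation whose amplitude grows as
  `neck_compensation_gain·u` (up to 8 deg/s and 0.6 m/s²), emulating
  the compensatory lateral/forward neck flexion seen late in fatiguing
  lifts.
* Per-subject variation is a multiplicative log-normal jitter
  (σ = 0.08) on the rates, slopes and the time-to-fatigue, seeded per
  subject from the cohort seed; trials are bitwise reproducible.

Default time-to-fatigue is 150 s, giving ~40 repetitions per subject
and ~1.2–1.3k labelled cycles for 30 subjects — the scale of a real
single-session fatigue study and comfortably desk-sized. The OFS
sampling rate, never fixed by such hardware, defaults to 100 Hz.

What the generator does **not** emulate: Hill-type muscle dynamics,
electrode artifacts and sweat-induced drift, motion artifacts below
15 Hz, non-monotone perceived-exertion reports, and early termination
through incomplete range of motion. Passing tests therefore demonstrate
that the pipeline recovers the canonical fatigue signatures when they
are present with realistic effect sizes and noise — not that it would
survive every pathology of field recordings.

## Conditioning choices

All filters are applied forward–backward (zero phase): the effective
order doubles, but cycle boundaries stay aligned across sensors, which
matters because the angle sensor's peak times slice every other stream.
The angle low-pass is a 4th-order Butterworth at 0.5 Hz (the curl
fundamental is 0.22–0.35 Hz, so the cycle passes with ≤5% attenuation
while measurement noise is removed); the family/order mirror the EMG
band-pass for uniformity. Moving averages (200 ms EMG envelope, 30 ms
IMU smoothing) use centered odd-length windows — widths round up to the
next odd sample count (30 ms at 128 Hz → 5 samples) — with
shrink-at-edges handling so constants are preserved exactly and no
padding artifacts leak into edge cycles. The per-recording MVC summary
is the envelope mean over the central 3 s of the 5 s hold (ramp-up and
release excluded); the reference MVC is the mean of three holds.

## Cycle detection and labeling

Peak picking on the filtered angle uses two scale-free parameters: a
minimum peak separation of half the autocorrelation-estimated cycle
period and a minimum prominence of 20% of the signal range. Both adapt
to cycle slowing and ROM decay without tuning. Maximum-flexion versus
maximum-extension peaks differ only by a half-cycle shift, so the
maximum-angle peak is used. Cycle labels use the linearly interpolated
Borg rating at the window midpoint (ends would bias the label toward
the neighbouring state). The state cut-points (LF ≤ 3 < MOF ≤ 6 < HF)
are configuration with CR10-convention defaults.

## Spectral estimators

MNF and MDF use a Hann-tapered periodogram with the DC bin excluded and
constant detrending (the angle has a ~70° offset that is posture, not
oscillation). MDF is the smallest frequency at which cumulative power
reaches half the total, so its cumulative power below lies within one
grid step of 0.5 by construction.

The IMNF uses a complex Morlet CWT (`cmor1.5-1.0`) on 48 log-spaced
frequencies up to the Nyquist rate; at each instant the power-weighted
mean frequency is formed with trapezoid weights over the frequency grid
(plain sums over a log grid would bias the centroid low by ~15%), and
the IMNF is the time average. Against independent oracles this
estimator is within 1% of the periodogram MNF for stationary band
noise, and within 4% for tones and linear chirps (the residual bias
comes from the wavelet's constant-Q smoothing on a log grid). The
frequency floor is 8 Hz for EMG (content starts at 15 Hz; lower scales
are pure cost) and one cycle-fundamental for the angle signal, whose
energy lies far below 1 Hz.

EMG spectral features are computed on the band-passed signal, not the
envelope: enveloping destroys the 15–450 Hz content these indices
measure, and they are scale-invariant so MVC normalization is
irrelevant to them.

## Normalization

Non-frequency features are divided by the subject's own first-cycle
value (f_n = f_i/f_0); frequency features are already inter-subject
comparable and pass through. Because f_0 is per subject, normalization
can precede the train/test split without cross-subject leakage. A zero
f_0 is refused with the feature named rather than epsilon-padded —
with the default generator this cannot occur, and on real data it
flags a dead channel rather than hiding it. Baseline-subtracted IMU
means can make f_0 small and the normalized feature large; tree
ensembles split on thresholds and are insensitive to such scale
outliers, so no additional guard is applied.

## Model selection and evaluation

The split is a seeded random subject-level partition
(|train| = round(0.7·n)); stratification is undefined at subject level
because every subject traverses all three states. Grid-search scoring
is mean LOOCV fold accuracy with ties broken by mean weighted F1 and
then grid order; all candidates share the same folds. The default
LightGBM grid is a 2×2 neighborhood (num_leaves {31, 181} ×
min_child_samples {8, 20}, 100 trees); the other four families run
their single reference configuration. All estimators are
single-threaded with fixed seeds, so repeated runs are identical.

Split importance counts ensemble splits per feature (verified in tests
against a brute-force traversal of the dumped booster); ties keep
canonical feature order, and top-k selections are nested by
construction. The ablation protocol re-ranks within each sensor subset
before truncating to that subset's top-k (7 EMG, 8 OFS, 5/4 single-IMU,
10 IMUs, 13 IMUs+OFS, 33 all), then retrains and evaluates on the
held-out subjects.

Metrics come from the 3×3 confusion matrix. For single-label multiclass
data, micro-averaged precision, recall and F1 all equal accuracy — an
identity the tests assert on random matrices — so reported tables in
which precision differs from accuracy imply support-weighted averaging.
Both modes are computed and stored side by side in every report, with
weighted as the default for tabulation; percentages are rounded to one
decimal.

## Known limitations

* The generator's effect sizes for kinematic decline are free
  parameters chosen as realistic defaults, not measured constants.
* The IMNF inherits the CWT's constant-Q bias (a few percent high for
  narrowband signals near the grid edges).
* Cycle detection assumes a quasi-periodic angle trace; it will not
  segment recordings without discernible repetitions (it returns an
  empty window list with a warning instead).
* Accuracies obtained on the synthetic cohort characterize the
  pipeline's ability to recover a planted, well-separated fatigue
  process; they are not estimates of performance on field recordings.
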