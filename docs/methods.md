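# Methods

## Problem and scope

`breathfit` classifies respirator seal integrity (fit vs. poor fit) from
three signals sampled at 10 Hz inside the mask dead space: absolute
pressure (hPa), temperature (°C) and relative humidity (%RH). The package
covers the offline analysis pipeline — synthetic data generation,
preprocessing, segmentation, feature extraction, model evaluation — not the
sensor firmware, wireless transport or any on-device deployment concerns.

## Synthetic signal model

No public dataset of intra-mask tri-channel recordings exists, so the
generator is a first-class component rather than a test fixture. It builds
each session cycle by cycle:

* **Breathing rate.** One rate per subject, uniform on `rate_range_bpm`
  (default 12–16 breaths/min, the typical resting band). Each cycle's
  period is the subject period times `1 + ε`, ε normal with coefficient of
  variation `cycle_jitter_cv` (default 0.05, clipped at ±0.3).
* **Phase split.** The inspiratory fraction δ of each cycle is drawn from
  Normal(0.40, 0.03) truncated to [0.2, 0.6]; resting inspiration is
  shorter than expiration.
* **Pressure.** Baseline 1013 hPa; a raised-cosine hump of amplitude
  `A = pressure_amp_hpa · (1 − λ)` is subtracted over the inspiratory
  sub-phase and added over the expiratory sub-phase (default amplitude
  0.6 hPa, per-subject variation CV 0.10). λ ∈ [0, 1] is the block's leak
  severity: a leak diverts flow around the filter and attenuates the
  oscillation multiplicatively. This amplitude law is exact in the
  noiseless generator (verified to machine precision in tests).
* **Microclimate.** Temperature and humidity relax first-order (time
  constant `microclimate_tau_s`, default 0.4 s) toward exhalation targets
  during expiration and toward ambient during inspiration. Exhalation
  targets default to 33 °C / 98 %RH against a 24 °C / 55 %RH ambient —
  exhaled air is warm (≈31–35 °C) and near saturation — and the exhalation
  increment scales by `(1 − λ)`: a leak vents the warm moist plume. Under
  leak, each channel's phase timing is independently jittered by
  Normal(0, `phase_noise_sd_s`·λ) per cycle, modelling leak-induced
  decorrelation between the mechanical and microclimate channels.
* **Noise.** Per-channel random-walk drift (steps 0.002 hPa / 0.003 °C /
  0.02 %RH per sample) and white noise (0.02 hPa / 0.05 °C / 0.5 %RH),
  magnitudes chosen as plausible for a consumer combined
  pressure/humidity/temperature sensor die.

Cycles start at inspiration onset, which is where the temperature trace
peaks (end of the previous exhalation); the generator returns these
boundary times, the per-cycle δ and λ as ground truth.

The **default session plan** mirrors a standard fit-test protocol:
~21 min labelled fit (proper fit 6 + 3 min, reading aloud 2 min, passed
seal test 10 min), ~16 min labelled poor-fit (tube leak, loose and
displaced at 2 min each with λ = 0.6/0.7/0.8, failed seal test 10 min at
λ = 0.7), and ~13 min of unlabelled transitions — 37 labelled minutes in a
50 min session. At 12–16 bpm a 20-subject cohort yields ≈10,000–12,000
labelled cycles with a ≈55–60 % / 40–45 % fit/poor-fit split. The leak
severities are tunable assumptions: no quantitative leak effect sizes are
available to calibrate against, so they encode "clearly degraded but
nonzero" seal states.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: motion and speech artefacts beyond amplitude
labels, ambient temperature/humidity weather, inter-breath correlation
structure (each cycle's parameters are independent), filter clogging,
CO₂, and realistic overlap between fit and poor-fit feature distributions.
With the default leak severities the synthetic classes are nearly
separable, so classifier scores near 1.0 on synthetic cohorts demonstrate
pipeline correctness (no leakage, labels aligned with physics), not
expected field performance.

## Preprocessing

Fourth-order Butterworth bandpass, corners 0.1 and 0.42 Hz: drift below
0.1 Hz and noise above 0.42 Hz are outside the breathing band. "Fourth
order" is read as the total order of the bandpass transfer function (an
order-2 prototype transformed to bandpass), so the corners sit at −3 dB of
a single pass; the alternative reading is available via the `order`
parameter. The filter runs as cascaded second-order sections, zero-phase
(forward–backward, which squares the magnitude response) with
odd-reflection padding of 3× the order; a causal single-pass mode exists
for streaming parity but is not the canonical path. Each channel is then
z-scored to mean 0 / SD 1 using the population-SD convention (the
convention is arbitrary but fixed and stated so results reproduce).
Zero-variance channels and NaN gaps are hard errors — silent imputation
would corrupt cycle timing.

A consequence worth stating explicitly: a 0.1–0.42 Hz passband keeps only
the fundamental and (partially) the second harmonic of a 0.2–0.27 Hz
breathing waveform. Cycle *periods* survive filtering exactly, but
sub-cycle asymmetry is progressively symmetrized, biasing the detected
valley toward mid-cycle (Δ_insp → 0.5). Timing-fidelity checks against
generator ground truth therefore run on standardized but unfiltered
noiseless signals, where the drift-suppression filter has nothing to do;
on filtered data the Δ_insp feature still carries class information (leak
alters waveform shape) but is not an unbiased estimate of the physiological
inspiratory fraction.

## Segmentation

Strict local extrema are detected on the preprocessed temperature channel
(plateaus resolve to their first index, endpoints never qualify), then
thinned greedily — highest amplitude first, ties to the earlier index —
until any two retained extrema are at least `mpd` samples apart
(default 23 samples = 2.3 s, a 26 BPM ceiling). Valleys use the inverted
signal with the same mpd. The implementation is cross-checked for exact
equality against a brute-force reference (exhaustive extrema scan plus
greedy suppression) on 1,000 random series including plateau- and tie-rich
integer series.

Cycles are consecutive peak pairs containing exactly one retained valley;
valleys outside the peak span are dropped, and intervals with zero or
multiple valleys are discarded as artefacts. Adjacent cycles share their
boundary peak; slices use inclusive bounds `[p_initial, p_final]` applied
identically to all three channels. On noiseless synthetic data the
recovered periods match ground truth within one sample and Δ_insp within
±0.02; the first and last cycles of a block can be lost to edge effects
(the recording's first inspiration onset is not a detectable peak), so a
60 s block at 12 bpm with 12 true cycles yields 10–11 detected ones.

Labelling rules are this package's own (the transition behaviour has no
published reference): a cycle or window takes the majority label over its
span when the majority fraction reaches `label_purity` (default 0.8), and
is discarded otherwise or when the majority is `other`. Sliding windows
default to 5 s with 2 s overlap (50 samples, step 30). Per-segment
re-standardization exists behind `per_segment_zscore` but is off by
default: z-scoring each cycle per channel would pin the per-channel SD
feature at 1 and null the phase-mean features, so the session-level
z-score is canonical. A `swap_phases` flag flips the inspiration/expiration
reading of the triplet for users who prefer the opposite anchor-channel
interpretation.

## Features

22 cycle features in fixed canonical order (channels ordered pressure,
humidity, temperature): `insp_time_prop` (a fraction in (0,1); the
expiratory complement is deliberately not stored — it is collinear), 3×
peak-to-peak, 6× phase means (inspiratory slice `[p_initial, v]`,
expiratory `[v, p_final]`, inclusive, sharing the valley sample), 3× SD,
3× skewness, 3× kurtosis, 3× median. Skewness is the Fisher–Pearson
standardized third moment and kurtosis is excess kurtosis, both
bias-uncorrected population forms; conventions are fixed for
reproducibility. Phase means are computed on the preprocessed signals
(raw-unit extraction is possible by skipping preprocessing, but
standardized units are canonical). Constant-valued slices are errors, not
NaNs: higher moments are undefined there. The 18-feature window schema
(per-channel ptp, mean, SD, skew, kurt, median) is this package's own
definition — phase-based features need a phase boundary that an arbitrary
window lacks.

## Modeling and validation

SMOTE is implemented in-package: synthetic minority rows are
`a + u(b − a)` for a random minority row `a`, one of its k = 5 nearest
minority neighbours `b` (Euclidean, via scikit-learn's neighbour search)
and `u ~ U[0,1]`, appended until classes balance exactly. It is applied to
the training portion of each fold only, after the split; test folds are
never resampled (audited by row identity in tests).

Families: `RandomForestClassifier`, `SVC` (RBF, behind a standardizing
pipeline step), `XGBClassifier`. Default hyperparameters and the small
grid-search grids are desk-scale choices (RF estimators {100, 300}, depth
{∞, 10}, min-leaf {1, 5}; SVM C {0.1, 1, 10}, gamma {scale, 0.01, 0.1};
boosted trees learning rate {0.05, 0.1}, depth {3, 6}, rounds {100, 300},
subsample {0.8, 1.0}). Grid search maximizes mean inner-fold F1 with ties
going to the first point in documented grid order; it is off by default in
`evaluate` (the defaults already saturate synthetic cohorts) and available
via `search=True` / `--grid-search`.

Validation: stratified seeded 5-fold, and LOSO with one fold per subject
(a `group_size` parameter generalizes to leave-N-subjects-out). Per fold:
F1 with poor_fit positive, ROC-AUC from probability or margin scores
(undefined and reported as null when the held-out subject saw one class),
and a 2×2 confusion matrix with rows = true (poor_fit, fit). The headline
summary is mean ± SD of per-fold F1; a pooled confusion matrix is
secondary. LOSO subject disjointness is asserted at runtime on every fold.

## Reproducibility and problem sizes

A single global seed expands into per-stage substreams (simulation, fold
shuffling, SMOTE, model seeds) via `numpy.random.SeedSequence`; per-subject
simulation streams are keyed by `(seed, subject_index)`, so cohorts are
reproducible and subjects independent. Re-running a config reproduces the
feature table and report byte-for-byte, and the run manifest records every
resolved parameter plus library versions.

Test problem sizes are chosen for quick, deterministic runs: the
segmentation-strategy direction check uses eight subjects on a
0.35×-scaled protocol across five generator seeds (the direction —
cycle-based ≥ window-based per family and scheme, cycle LOSO F1 ≥ 0.90 —
is stable at this scale because it is driven by the leak physics, not the
cohort size); the cycle-identity check runs a four-subject full-length
cohort; unit tests use single short sessions. The full 20-subject default
cohort runs end to end in about a minute and is exercised by the worked
example rather than the test suite.

## Known limitations

* Synthetic-only validation: no claim transfers to real recordings without
  recalibrating generator noise, leak effect sizes and class overlap.
* The bandpass symmetrization of Δ_insp (above) makes the stored time
  ratio a shape feature rather than a physiological measurement.
* Binary labels only; graded fit levels would need a different label model
  and metrics.
* The causal filtering mode changes cycle timing (group delay) and is not
  wired into the canonical pipeline; streaming segmentation is out of
  scope.
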