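# breathfit

Continuous respirator-fit detection from intra-mask breathing signals.

Tight-fitting industrial respirators only protect while the facial seal
holds, but standard fit tests (qualitative aerosol-taste tests, quantitative
particle-count tests) are periodic: a seal that degrades mid-shift goes
unnoticed. A small sensor in the mask dead space records absolute
**pressure**, **temperature** and **relative humidity** at 10 Hz; breathing
modulates all three — inhalation pulls sub-ambient pressure through the
filter and draws in cool dry air, exhalation pushes supra-ambient pressure
and floods the dead space with warm (≈31–35 °C), near-saturated air. A leak
vents that plume and diverts flow, attenuating and decorrelating the
cycle-synchronous oscillations. `breathfit` turns those series into a
binary fit / poor-fit classification:

1. **Preprocess** — fourth-order Butterworth bandpass (0.1–0.42 Hz,
   zero-phase) plus z-score normalization per channel.
2. **Segment** — breathing cycles as validated peak–valley–peak triplets
   `[P_initial, V, P_final]` on the temperature channel (minimum peak
   distance 23 samples = 2.3 s = a 26 BPM ceiling), with

   ```
   T_cycle = (P_final − P_initial) / fs
   Δ_insp  = (V − P_initial) / (P_final − P_initial),   Δ_exp = 1 − Δ_insp
   ```

   or, alternatively, fixed 5 s sliding windows with 2 s overlap
   (50 samples per signal).
3. **Featurize** — 22 named features per cycle (Δ_insp; peak-to-peak,
   inspiratory/expiratory means, SD, skewness, kurtosis and median per
   channel), or an 18-feature window variant without phase-based terms.
4. **Classify** — random forest, RBF SVM or gradient-boosted trees
   (xgboost), with SMOTE balancing applied to training folds only,
   evaluated under stratified 5-fold and leave-one-subject-out (LOSO)
   cross-validation; F1 (positive class = poor fit), ROC-AUC and confusion
   matrices per fold.

Because raw study data of this kind is not openly available, the package
includes a first-class physics-informed generator (`breathfit.synth`) that
simulates labelled cohorts — cycle-synchronous tri-channel signals, a
protocol plan of fit / leak / loose / displaced blocks, leak-severity
physics, drift and sensor noise — with per-cycle ground truth, so every
stage can be tested against a known answer.

## Worked example

Run the full pipeline on a synthetic cohort from a YAML config:

```yaml
# demo.yaml
outdir: demo_run
seed: 1
mode: cycles
model_family: gradient_boosted_trees
scheme: loso
synth:
  n_subjects: 6
  session_plan:
    - {duration_s: 180, label: fit, condition: proper_fit}
    - {duration_s: 30, label: other, condition: transition}
    - {duration_s: 120, label: fit, condition: reading_aloud}
    - {duration_s: 30, label: other, condition: transition}
    - {duration_s: 120, label: poor_fit, condition: tube_leak, leak: 0.6}
    - {duration_s: 30, label: other, condition: transition}
    - {duration_s: 120, label: poor_fit, condition: loose, leak: 0.7}
```

```text
$ breathfit -v run --config demo.yaml
INFO breathfit: simulating 6 subjects (630 s sessions)
INFO breathfit: cycles mode: 776 labelled segments
INFO breathfit: feature table: 776 rows x 26 columns
INFO breathfit: gradient_boosted_trees/loso/cycles: F1 = 0.9986 ± 0.0032 over 6 folds
F1 = 0.9986 ± 0.0032 over 6 folds; artifacts in demo_run
```

776 breathing cycles were detected, labelled by protocol block and scored
under LOSO: held-out subjects are classified almost perfectly because the
simulated leak (λ = 0.6–0.7) attenuates pressure oscillation amplitude by
the factor (1 − λ) and damps the exhalation temperature/humidity excursions
— exactly the physics the features encode. `demo_run/` holds the feature
table, a JSON report with per-fold F1/ROC-AUC/confusion matrices, and a
manifest of every resolved parameter and library version; re-running the
same config reproduces all artifacts byte-for-byte.

The segmentation-strategy comparison (`breathfit compare`) evaluates all
three families under both segmentations and both schemes. On an
eight-subject cohort with a 0.35×-scaled default protocol (seed 1):

```text
Model                   Validation        Sliding Window         Cycle-Based
random_forest           kfold               99.94 ± 0.12       100.00 ± 0.00
random_forest           loso                99.88 ± 0.20       100.00 ± 0.00
svm_rbf                 kfold               99.88 ± 0.14       100.00 ± 0.00
svm_rbf                 loso                99.88 ± 0.20       100.00 ± 0.00
gradient_boosted_trees  kfold               99.88 ± 0.14        99.92 ± 0.16
gradient_boosted_trees  loso                99.83 ± 0.22        99.92 ± 0.20
```

Cells are mean ± SD of per-fold F1 in percent; any cell where cycle-based
segmentation underperforms its window counterpart is flagged `(!)`. The
full default cohort (20 subjects, 50 min sessions, ~10,400 labelled cycles)
takes about a minute end to end.

## Command-line interface

```
breathfit simulate   --config synth.yaml --out dir/ --seed N
breathfit preprocess --in rec.csv --out rec_pp.csv [--low 0.1 --high 0.42 --order 4]
breathfit segment    --in rec_pp.csv --labels labels.csv --mode cycles|windows --out features.csv
breathfit evaluate   --features features.csv --model rf|svm|xgb --scheme kfold|loso --seed N --report report.json
breathfit run        --config run.yaml
breathfit compare    --config run.yaml
```

All file formats are plain CSV: recordings as
`time_s,pressure_hpa,temperature_c,humidity_rh`, labels as
`subject_id,session_id,start_s,end_s,label,condition`, feature tables as
`subject_id,session_id,provenance,label,<feature columns>` with the
canonical feature order given by `breathfit.CYCLE_FEATURE_NAMES` /
`WINDOW_FEATURE_NAMES`.

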