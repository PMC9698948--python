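# pulseqc

Beat-to-beat quality assessment of radial pulse pressure waveforms.

Skin-surface tonometry of the radial artery yields a blood-pressure
waveform (BPW) whose fidelity depends critically on the sensor's contact
pressure: too much (or too little) holding force distorts individual
pulses, and because motion-artifact spectra overlap the pulse spectrum the
distorted pulses cannot be filtered — they have to be recognized and
discarded. `pulseqc` is a pipeline for developing and validating exactly
that screen. It is aimed at physiological-signal researchers and
wearable-device engineers who need a reproducible, fully ground-truthed
test bed for pulse-quality classifiers.

The package provides:

* **`pulseqc.synth`** — a cohort simulator emulating a two-arm protocol
  (one recording at appropriate contact pressure, one at a deliberately
  higher pressure, per subject), with per-beat ground-truth onsets and
  quality labels. Defaults state the emulated population: 60 subjects, HR
  69.57 ± 10.73 beats/min, 60 s at 1024 Hz, 98.0 % clean beats in the
  appropriate arm, 78.2 % distorted beats in the higher arm.
* **`pulseqc.segment`** — pulse-foot detection (slope-threshold upstroke
  search, backward walk to the preceding minimum) and beat segmentation.
* **`pulseqc.features`** — the 40 harmonic indices per beat, n = 1..10:
  amplitude proportions `C_n = a_n / Σ a_k`, their beat-to-beat
  coefficients of variation `CV_n` (%), phase angles `P_n` (degrees,
  cosine convention, beat-onset origin), and their standard deviations
  `P_n_SD` (computed on the unwrapped phase sequence).
* **`pulseqc.classify`** — eight classifiers (SVM, MLP, GNB, DT, RF, LR,
  LDA, KNN) under threefold cross-validation, leave-one-subject-out (LOSO,
  majority vote per held-out recording), and a subject-grouped 8:2
  hold-out.
* **`pulseqc.metrics`** — exact confusion-matrix metrics, Mann-Whitney
  ROC AUC, and Welch-test group comparisons with `*` (p < 0.05) / `+`
  (0.05 < p < 0.1) flags.

See `docs/methods.md` for the signal model, parameter rationale and
limitations.

## Worked example

```python
from pulseqc import (
    SimulationConfig, generate_cohort, build_feature_table,
    leave_one_subject_out, compare_feature_groups,
)

config = SimulationConfig(n_subjects=12, duration=30.0, seed=42)
records = generate_cohort(config)            # 24 records, 2 per subject
features = build_feature_table(records)      # 773 labelled beats x 40 indices

result = leave_one_subject_out(features, methods=["RF", "KNN"], seed=42)
print(result.table[["method", "tp", "fn", "tn", "fp", "accuracy", "auc"]])
```

```
method  tp  fn  tn  fp  accuracy  auc
    RF  12   0  12   0     100.0  1.0
   KNN  12   0  12   0     100.0  1.0
```

Each of the 24 recordings was classified by majority vote over its beat
predictions with that subject held out of training; both methods separate
the appropriate- from the higher-pressure recordings perfectly — expected
on synthetic data, where all subjects share one waveform template and the
variability indices carry a clean regime signature.

The index-level contrast behind that separation (`compare_feature_groups`,
appropriate = group A vs higher = group B):

```
        mean_a    sd_a  mean_b     sd_b  p_value flag
C2       0.227   0.004   0.226    0.027    0.206
CV2      2.381   1.181  14.415    2.611    0.000    *
P2    -155.089  31.474 -85.133  130.580    0.000    *
P2_SD   18.877  42.010  94.338   85.237    0.000    *
```

`CV2` and `P2_SD` — beat-to-beat instability of the second harmonic — are
several times larger under the higher contact pressure and flagged
significant, mirroring the pattern that motivates using these indices as
quality features.

A command-line interface wraps the same functions:

```sh
pulseqc simulate --out cohort/ --seed 1
pulseqc features --in cohort/ --out features.tsv
pulseqc evaluate --features features.tsv --protocol loso --methods RF --seed 1 --out results.json
pulseqc compare --features features.tsv --out comparison.tsv
pulseqc run --out full_run/ --seed 1      # the whole pipeline at once
```

## Acceptance script

`scripts/acceptance.py` exercises the complete pipeline from scratch —
simulation, segmentation, feature extraction, all three evaluation
protocols and the regime comparison — on a freshly generated cohort:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
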