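# Methods

`pulseqc` models the problem of screening beat-to-beat quality of radial
blood-pressure waveforms (BPW) acquired by skin-surface tonometry. When the
sensor's contact pressure is inappropriate, motion artifacts and vessel
compression distort individual pulses; because the artifact spectrum
overlaps the pulse spectrum, distorted pulses cannot be repaired and must be
identified and discarded before any index calculation. The package provides
(i) a synthetic generator that emulates a two-arm contact-pressure protocol
with per-beat ground truth, (ii) beat segmentation, (iii) the 40 harmonic
indices used as features, and (iv) an evaluation harness for eight standard
classifiers under three protocols.

## Signal model

Each beat is a truncated Fourier (cosine) series of its own fundamental,

    x(t) = dc + sum_{n=1..10} a_n cos(2 pi n t / T + phi_n),

sampled at `round(T * fs)` points evenly spaced over one period. Because the
beat interval defines the fundamental, the harmonics sit exactly on rFFT
bins and decomposition of a noise-free beat recovers the generating
coefficients to machine precision (the round-trip tests assert 1e-6 /
1e-3 degrees).

The default template is the 10-harmonic series of an idealized radial
pulse: a linear systolic upstroke over the first 15 % of the beat, a linear
diastolic decay over the remainder, lightly smoothed (Gaussian, 1 % of the
period), amplitudes normalized to a1 = 1, dc = 2 (arbitrary pressure
units). Template phases are calibrated so the waveform minimum — the pulse
foot — falls exactly on the beat boundary. This matters numerically: a foot
formed by an ongoing diastolic decay meeting the next upstroke is sharply
localized, so its position is well conditioned under beat-to-beat jitter
(measured position SD under the higher-pressure regime's jitter is ~1-3
samples at 1024 Hz). Symmetric or flat-footed templates make the foot
position ill-conditioned and were rejected for that reason.

## The simulated cohort (the stated world)

Defaults encode the emulated study population: 60 subjects, resting heart
rate 69.57 +/- 10.73 beats/min (subject-level draw, clamped to 40-120 and
shared between a subject's two recordings), 60 s per recording at 1024 Hz,
beat-to-beat period CV 3 % truncated at 3 SD. Each subject contributes one
recording per contact-pressure regime:

| parameter | appropriate | higher |
|---|---|---|
| amplitude jitter CV (per harmonic, %) | 2 | 6 |
| phase jitter SD (per harmonic, deg) | 2 | 4 |
| distorted-beat probability | 0.020 | 0.782 |

The distorted-beat probabilities are the study's annotated quality mixture
(98.0 % clean at appropriate pressure, 78.2 % distorted at higher
pressure). The jitter ratios (3x amplitude, 2x phase) are this package's
choice: they reproduce the reported qualitative signature — CV_n and P_n_SD
inflated roughly 2-3x under higher contact pressure — while keeping
beat-to-beat foot-timing noise in the physiologic few-millisecond range.
The nominal contact pressures (about 68 and 152 mmHg) are condition labels
only and never enter the signal model.

Distorted beats are drawn per beat (Bernoulli) and pass through one of
three artifact channels (uniform mixture by default):

* **baseline drift** — a partial-cycle sinusoid (0.3-0.8 cycles, random
  phase, 0.4-1.0 a1) added across the beat;
* **spike** — a Gaussian transient (width 2 % of the beat, amplitude
  0.5-1.5 a1, random sign and position);
* **damping** — harmonics 4-10 multiplied by 0.15-0.45 before synthesis.

What a green test does and does not establish: the generator reproduces the
protocol's structure (per-subject pairing, quality mixture, index-level
directionality) but not real tonometry — no baseline wander between beats,
no sensor drift, no correlated artifact runs, no morphology differences
between subjects beyond heart rate. Classification results on this cohort
are therefore a property check of the pipeline (features carry the quality
signal; protocols are leak-free), not a reproduction of the published
real-data AUCs.

## Segmentation

Slope-threshold foot detection: samples whose first difference exceeds
`k = 2` times the record-level robust SD of the derivative (1.4826 x MAD,
falling back to the plain SD when the MAD collapses on mostly-flat signals)
mark systolic upstrokes; each accepted upstroke is traced backwards to the
preceding local minimum (strict descent, so plateaus stop the walk). A
refractory period of `60/max_hr` seconds suppresses double triggers, and
segments outside the 0.25-2.0 s physiologic period gate (heart rates
30-240) are dropped and logged. Intervals are half-open `[onset, end)`,
0-based. On artifact-free default cohorts every truth onset is recovered
within 8 samples (< 10 ms) with no spurious detections.

## The 40 indices

For each beat, `C_n = a_n / sum_k a_k` (amplitude proportion; the
alternative convention `a_n / a1` is behind `normalization="first"`), and
`P_n = phi_n` in degrees wrapped to (-180, 180], cosine convention with the
beat onset as time origin. The variability indices need a window of beats:
by default the whole record, i.e. every beat of a record shares the
record-level `CV_n = 100 * SD(C_n)/mean(C_n)` and `P_n_SD = SD(P_n)`; a
centered sliding window of `w` beats is available. SDs use the n-1
denominator; phase SDs are computed after unwrapping the window's phase
sequence (period 360) to avoid the +/-180 seam. Beats with any undefined
feature (zero-amplitude harmonic, unmatched label, window of one beat) are
dropped, never imputed.

## Classification protocols

Class "1" is high quality. Every method runs inside a pipeline whose
standardizer is fitted on the training portion only. Hyperparameters are
fixed, documented defaults (RF 100 trees; KNN k = 5; MLP one hidden layer
of 32 units, max 500 iterations; SVM RBF C = 1; LR/LDA/GNB/DT library
defaults), all overridable.

* **Threefold CV** — stratified at the beat level (subject-grouped folds
  available via `grouped=True`); per-fold and averaged metrics.
* **Leave-one-subject-out** — all of a subject's beats held out per fold;
  each held-out recording receives one label by majority vote over its beat
  predictions, ties broken toward "low" (conservative for a quality
  screen); its score is the fraction of beats predicted high-quality, the
  recording's truth is the majority truth of its beats. Confusion counts
  accumulate over recordings (beats, with `unit="beat"`). Subject-id
  bookkeeping raises `LeakageError` if a held-out subject appears in the
  training pool.
* **Hold-out** — subjects split 8:2; threefold CV on the training portion
  plus a final hold-out row.

Accuracy is reported in percent, sensitivity/specificity/AUC as fractions
in evaluation tables; the `metrics` module returns all three in percent
(exact rational arithmetic, rounded only for display). AUC is the
Mann-Whitney rank statistic with ties counted 1/2, asserted equal to
exhaustive pair counting in tests.

## Group comparisons

Per-index two-group comparisons use Welch's unequal-variance two-sided t
test by default (the test behind the study's figures is unnamed); a paired
variant is available since both pressures were measured on the same
subjects. Flags follow the figure convention: `*` for p < 0.05, `+` for
0.05 < p < 0.1. No multiple-testing correction is applied, matching the
source analysis.

## Numerical choices and degenerate inputs

* Phases wrap to (-180, 180]; -180 maps to +180.
* Zero-variance groups with equal means compare at p = 1.
* A beat needs at least 21 samples (2 x 10 harmonics + 1) to be
  decomposable; shorter beats are errors.
* Flat or upstroke-free records yield zero onsets with a warning, not an
  exception; fewer than two onsets segment to an empty list.
* All randomness flows from `numpy.random.default_rng(seed)`; identical
  configs give byte-identical cohorts and identical evaluation tables.

## Known limitations

* The synthetic cohort shares one template across subjects; interindividual
  waveform morphology is not modeled, which makes the classification task
  easier than on real data (recording-level AUCs saturate near 1.0).
* The LOSO permutation null is evaluated at the beat level because the
  recording-level null over 120 recordings has Monte-Carlo SD ~0.05.
* CV_n/P_n_SD with the default whole-record window make all beats of a
  record share 20 of the 40 features; with beat-level fold stratification
  this is a deliberate re-reading of an ambiguous convention (both window
  modes are provided).
* Group comparisons at the beat level treat beats as independent units, as
  the source analysis appears to; with record-level features repeated per
  beat this overstates the effective sample size.
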