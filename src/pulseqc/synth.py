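"""Synthetic radial blood-pressure-waveform (BPW) cohorts.

Emulates a two-arm tonometry protocol in which every subject contributes one
one-minute recording made at an appropriate sensor contact pressure and one
made at a deliberately higher contact pressure.  Each beat is a ten-harmonic
cosine series; regime-dependent beat-to-beat jitter plus sporadic motion
artifacts produce the high/low-quality beat mixture that segmentation,
feature extraction and classification are exercised against.

Every generated record carries its ground truth (beat-onset sample indices
and per-beat quality labels), so downstream stages can be validated exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "N_HARMONICS",
    "HarmonicTemplate",
    "RegimeSpec",
    "SimulationConfig",
    "WaveformRecord",
    "default_template",
    "wrap_phase_deg",
    "synthesize_beat",
    "generate_record",
    "generate_cohort",
]

N_HARMONICS = 10
HARMONICS = np.arange(1, N_HARMONICS + 1)

ARTIFACT_MODELS = ("baseline_drift", "spike", "damping", "mixture")
REGIME_LABELS = ("appropriate", "higher")

# physiologic clamp for subject-level resting heart rate draws (beats/min)
_HR_LO, _HR_HI = 40.0, 120.0


def wrap_phase_deg(phi):
    """Wrap angles in degrees onto the interval (-180, 180]."""
    phi = np.asarray(phi, dtype=float)
    wrapped = -(((-phi + 180.0) % 360.0) - 180.0)
    return float(wrapped) if wrapped.ndim == 0 else wrapped


@dataclass(frozen=True)
class HarmonicTemplate:
    """Harmonic content of one nominal beat.

    Parameters
    ----------
    dc : float
        Pressure offset (arbitrary units).
    amplitudes : sequence of 10 floats
        Cosine amplitudes a1..a10, all non-negative with a1 > 0.
    phases_deg : sequence of 10 floats
        Phases phi1..phi10 in degrees; wrapped to (-180, 180] on construction.
    """

    dc: float
    amplitudes: tuple
    phases_deg: tuple

    def __post_init__(self):
        amps = tuple(float(a) for a in self.amplitudes)
        phases = tuple(wrap_phase_deg(p) for p in self.phases_deg)
        if len(amps) != N_HARMONICS or len(phases) != N_HARMONICS:
            raise ValueError(f"exactly {N_HARMONICS} harmonics required")
        if any(a < 0 for a in amps):
            raise ValueError("harmonic amplitudes must be non-negative")
        if amps[0] <= 0:
            raise ValueError("fundamental amplitude a1 must be positive")
        object.__setattr__(self, "dc", float(self.dc))
        object.__setattr__(self, "amplitudes", amps)
        object.__setattr__(self, "phases_deg", phases)

    def as_arrays(self):
        return np.asarray(self.amplitudes), np.asarray(self.phases_deg)

    def to_dict(self):
        return {
            "dc": self.dc,
            "amplitudes": list(self.amplitudes),
            "phases_deg": list(self.phases_deg),
        }

    @classmethod
    def from_dict(cls, d):
        return cls(d["dc"], tuple(d["amplitudes"]), tuple(d["phases_deg"]))


# Ten-harmonic cosine series of an idealized radial pulse: a linear systolic
# upstroke over the first 15 % of the beat, a linear diastolic decay over the
# rest, lightly smoothed (Gaussian, 1 % of the period).  Phases are calibrated
# so the waveform minimum -- the pulse foot -- falls exactly on the beat
# boundary; the ongoing diastolic decay meeting the next upstroke makes the
# foot sharply localized, which keeps onset detection well conditioned under
# beat-to-beat jitter.  Amplitudes are normalized to a1 = 1.
_DEFAULT_AMPLITUDES = (
    1.0, 0.442876, 0.237947, 0.127114, 0.059421,
    0.017646, 0.006397, 0.017866, 0.020693, 0.018119,
)
_DEFAULT_PHASES_DEG = (
    -123.987307, -157.974613, 168.038084, 134.050788, 100.06351,
    66.076321, -147.91155, 178.101444, 144.114202, 110.126953,
)


def default_template() -> HarmonicTemplate:
    """Default beat template: an idealized radial pulse.

    Sharp systolic upstroke peaking about 15 % into the beat, monotone
    diastolic decay, and the foot (waveform minimum) exactly at the beat
    boundary.  Only the *relative* harmonic content matters downstream, and
    the template is fully configurable.
    """
    return HarmonicTemplate(dc=2.0, amplitudes=_DEFAULT_AMPLITUDES, phases_deg=_DEFAULT_PHASES_DEG)


@dataclass(frozen=True)
class RegimeSpec:
    """One contact-pressure regime of the measurement protocol.

    The nominal contact pressures (about 68 mmHg "appropriate", about
    152 mmHg "higher") are condition labels only; they never enter the
    signal model.  What distinguishes the regimes numerically is the
    beat-to-beat jitter and the artifact (distorted-beat) rate.
    """

    label: str
    template: HarmonicTemplate = field(default_factory=default_template)
    amplitude_jitter_cv: float = 2.0  # per-harmonic multiplicative CV, percent
    phase_jitter_sd: float = 2.0      # per-harmonic additive SD, degrees
    artifact_rate: float = 0.02       # probability a beat is distorted
    artifact_model: str = "mixture"

    def __post_init__(self):
        if self.label not in REGIME_LABELS:
            raise ValueError(f"label must be one of {REGIME_LABELS}")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must lie in [0, 1]")
        if self.amplitude_jitter_cv < 0 or self.phase_jitter_sd < 0:
            raise ValueError("jitter parameters must be non-negative")
        if self.artifact_model not in ARTIFACT_MODELS:
            raise ValueError(f"artifact_model must be one of {ARTIFACT_MODELS}")

    def to_dict(self):
        return {
            "label": self.label,
            "template": self.template.to_dict(),
            "amplitude_jitter_cv": self.amplitude_jitter_cv,
            "phase_jitter_sd": self.phase_jitter_sd,
            "artifact_rate": self.artifact_rate,
            "artifact_model": self.artifact_model,
        }

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        d["template"] = HarmonicTemplate.from_dict(d["template"])
        return cls(**d)


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters.

    Defaults state the emulated study population: 60 subjects, resting heart
    rate 69.57 +/- 10.73 beats/min, 1-min recordings sampled at 1024 Hz,
    98.0 % clean beats at the appropriate contact pressure and 78.2 %
    distorted beats at the higher contact pressure.
    """

    n_subjects: int = 60
    hr_mean: float = 69.57
    hr_sd: float = 10.73
    duration: float = 60.0        # seconds per recording
    sampling_rate: float = 1024.0  # Hz
    clean_fraction_appropriate: float = 0.980
    lowq_fraction_higher: float = 0.782
    regimes: tuple = None
    seed: int = 0
    hr_cv_beat: float = 0.03      # beat-to-beat period CV, truncated at 3 SD

    def __post_init__(self):
        if not 0.0 <= self.clean_fraction_appropriate <= 1.0:
            raise ValueError("clean_fraction_appropriate must lie in [0, 1]")
        if not 0.0 <= self.lowq_fraction_higher <= 1.0:
            raise ValueError("lowq_fraction_higher must lie in [0, 1]")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.regimes is None:
            appropriate = RegimeSpec(
                "appropriate",
                amplitude_jitter_cv=2.0,
                phase_jitter_sd=2.0,
                artifact_rate=1.0 - self.clean_fraction_appropriate,
            )
            higher = RegimeSpec(
                "higher",
                amplitude_jitter_cv=6.0,
                phase_jitter_sd=4.0,
                artifact_rate=self.lowq_fraction_higher,
            )
            object.__setattr__(self, "regimes", (appropriate, higher))
        else:
            object.__setattr__(self, "regimes", tuple(self.regimes))
        # the 10th harmonic of the fastest plausible beat must stay below Nyquist
        max_f0 = min(self.hr_mean + 3.0 * self.hr_sd, _HR_HI) / 60.0
        if self.sampling_rate < 2.0 * N_HARMONICS * max_f0:
            raise ValueError("sampling_rate too low for 10 harmonics at the fastest heart rate")

    def to_dict(self):
        return {
            "n_subjects": self.n_subjects,
            "hr_mean": self.hr_mean,
            "hr_sd": self.hr_sd,
            "duration": self.duration,
            "sampling_rate": self.sampling_rate,
            "clean_fraction_appropriate": self.clean_fraction_appropriate,
            "lowq_fraction_higher": self.lowq_fraction_higher,
            "regimes": [r.to_dict() for r in self.regimes],
            "seed": self.seed,
            "hr_cv_beat": self.hr_cv_beat,
        }

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        if d.get("regimes") is not None:
            d["regimes"] = tuple(RegimeSpec.from_dict(r) for r in d["regimes"])
        return cls(**d)


@dataclass
class WaveformRecord:
    """One subject-condition recording with optional synthetic ground truth."""

    subject_id: str
    regime: str
    sampling_rate: float
    samples: np.ndarray
    truth_onsets: np.ndarray = None
    truth_beat_labels: np.ndarray = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.truth_onsets is not None:
            self.truth_onsets = np.asarray(self.truth_onsets, dtype=int)
            if np.any(np.diff(self.truth_onsets) <= 0):
                raise ValueError("truth onsets must be strictly increasing")
            if self.truth_onsets.size and (
                self.truth_onsets[0] < 0 or self.truth_onsets[-1] >= self.samples.size
            ):
                raise ValueError("truth onsets outside the sample range")
        if self.truth_beat_labels is not None:
            self.truth_beat_labels = np.asarray(self.truth_beat_labels)
            if self.truth_onsets is None or len(self.truth_beat_labels) != len(self.truth_onsets):
                raise ValueError("one quality label per truth onset required")

    @property
    def n_beats(self):
        return None if self.truth_onsets is None else int(self.truth_onsets.size)

    @property
    def duration(self):
        return self.samples.size / self.sampling_rate


def _cosine_series(dc, amplitudes, phases_deg, n_samples):
    """Evaluate dc + sum_n a_n cos(2 pi n t/T + phi_n) on t = (0..n-1) * T/n."""
    frac = np.arange(n_samples) / n_samples
    arg = 2.0 * np.pi * HARMONICS[:, None] * frac[None, :] + np.deg2rad(phases_deg)[:, None]
    return dc + np.asarray(amplitudes) @ np.cos(arg)


def synthesize_beat(template: HarmonicTemplate, period: float, sampling_rate: float) -> np.ndarray:
    """Render one noise-free beat of the given template.

    The beat is sampled at ``round(period * sampling_rate)`` points evenly
    spaced over [0, period), so the fundamental sits exactly on a Fourier bin
    of the returned segment and harmonic decomposition round-trips to
    machine precision.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    n = int(round(period * sampling_rate))
    if n < 2 * N_HARMONICS + 1:
        raise ValueError("sampling_rate * period must be at least 21 samples")
    amps, phases = template.as_arrays()
    return _cosine_series(template.dc, amps, phases, n)


def _trunc_std_normal(rng, sd_limit=3.0):
    while True:
        z = rng.standard_normal()
        if abs(z) <= sd_limit:
            return float(z)


def _draw_heart_rate(rng, config):
    """Subject-level resting HR, normal draw clamped to a physiologic band."""
    for _ in range(1000):
        hr = rng.normal(config.hr_mean, config.hr_sd)
        if _HR_LO <= hr <= _HR_HI:
            return float(hr)
    raise RuntimeError("heart-rate distribution incompatible with physiologic band")


def _synthesize_labelled_beat(rng, regime, period, sampling_rate):
    """One jittered beat; returns (samples, quality label in {'high','low'})."""
    n = int(round(period * sampling_rate))
    amps, phases = regime.template.as_arrays()
    amps = amps.copy()
    if regime.amplitude_jitter_cv > 0:
        factors = 1.0 + regime.amplitude_jitter_cv / 100.0 * rng.standard_normal(N_HARMONICS)
        amps *= np.clip(factors, 0.05, None)
    if regime.phase_jitter_sd > 0:
        phases = wrap_phase_deg(phases + regime.phase_jitter_sd * rng.standard_normal(N_HARMONICS))

    distorted = rng.random() < regime.artifact_rate
    model = None
    if distorted:
        model = regime.artifact_model
        if model == "mixture":
            model = ARTIFACT_MODELS[rng.integers(3)]
        if model == "damping":
            amps[3:] *= rng.uniform(0.15, 0.45)

    x = _cosine_series(regime.template.dc, amps, phases, n)
    a1 = regime.template.amplitudes[0]
    if distorted and model == "spike":
        center = rng.uniform(0.15, 0.85) * n
        width = max(3.0, 0.02 * n)
        sign = -1.0 if rng.random() < 0.5 else 1.0
        x = x + rng.uniform(0.5, 1.5) * a1 * sign * np.exp(
            -0.5 * ((np.arange(n) - center) / width) ** 2
        )
    elif distorted and model == "baseline_drift":
        cycles = rng.uniform(0.3, 0.8)
        x = x + rng.uniform(0.4, 1.0) * a1 * np.sin(
            2.0 * np.pi * cycles * np.arange(n) / n + rng.uniform(0.0, 2.0 * np.pi)
        )
    return x, ("low" if distorted else "high")


def generate_record(config: SimulationConfig, subject_id, regime, rng=None, subject_hr=None) -> WaveformRecord:
    """Simulate one recording: jittered beats concatenated to the target duration.

    Per-beat periods are 60/HR with Gaussian beat-to-beat variability
    (CV ``config.hr_cv_beat``, truncated at 3 SD).  Each beat is distorted
    with the regime's artifact probability, so realized clean fractions
    converge to the configured quality mixture.
    """
    if isinstance(regime, str):
        matches = [r for r in config.regimes if r.label == regime]
        if not matches:
            raise ValueError(f"unknown regime label {regime!r}")
        regime = matches[0]
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if subject_hr is None:
        subject_hr = _draw_heart_rate(rng, config)

    fs = config.sampling_rate
    target = int(round(config.duration * fs))
    mean_period = 60.0 / subject_hr

    chunks, onsets, labels = [], [], []
    total = 0
    while total < target:
        period = mean_period * (1.0 + config.hr_cv_beat * _trunc_std_normal(rng))
        x, label = _synthesize_labelled_beat(rng, regime, period, fs)
        if total == 0 and x.size > target:
            raise ValueError("duration too short to hold a single beat")
        onsets.append(total)
        labels.append(label)
        chunks.append(x)
        total += x.size

    return WaveformRecord(
        subject_id=subject_id,
        regime=regime.label,
        sampling_rate=fs,
        samples=np.concatenate(chunks),
        truth_onsets=np.asarray(onsets, dtype=int),
        truth_beat_labels=np.asarray(labels),
    )


def generate_cohort(config: SimulationConfig) -> list:
    """Simulate the full cohort: two records per subject, one per regime.

    The subject's heart rate is drawn once and shared between their two
    recordings.  Fully reproducible: identical config (including seed)
    yields an identical cohort.
    """
    rng = np.random.default_rng(config.seed)
    width = max(2, len(str(config.n_subjects)))
    records = []
    for i in range(config.n_subjects):
        subject_id = f"s{i + 1:0{width}d}"
        hr = _draw_heart_rate(rng, config)
        for regime in config.regimes:
            records.append(generate_record(config, subject_id, regime, rng=rng, subject_hr=hr))
    return records
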