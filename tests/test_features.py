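"""Harmonic decomposition and the 40 beat indices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulseqc.features import (
    FEATURE_COLUMNS,
    HarmonicDecomposition,
    UndefinedFeatureError,
    amplitude_proportions,
    build_feature_table,
    decompose_beat,
    phase_angles,
    windowed_variability,
)
from pulseqc.synth import HarmonicTemplate, synthesize_beat, wrap_phase_deg


def _template(amps, phases, dc=0.0):
    amps = tuple(amps) + (0.0,) * (10 - len(amps))
    phases = tuple(phases) + (0.0,) * (10 - len(phases))
    return HarmonicTemplate(dc=dc, amplitudes=amps, phases_deg=phases)


def _decomp(amps, phases=None):
    amps = np.asarray(amps, dtype=float)
    phases = np.zeros(10) if phases is None else np.asarray(phases, dtype=float)
    return HarmonicDecomposition(0.0, amps, phases)


class TestDecomposeBeat:
    def test_pure_cosine_identity(self):
        beat = synthesize_beat(_template([1.0], [0.0]), 1.0, 1024.0)
        d = decompose_beat(beat)
        assert d.amplitudes[0] == pytest.approx(1.0, abs=1e-6)
        assert abs(d.phases_deg[0]) < 1e-4
        assert np.all(d.amplitudes[1:] < 1e-6)

    def test_constant_beat(self):
        d = decompose_beat(np.full(512, 3.5))
        assert d.dc == pytest.approx(3.5, abs=1e-12)
        assert np.all(d.amplitudes < 1e-9)

    def test_too_short_beat_rejected(self):
        with pytest.raises(ValueError):
            decompose_beat(np.zeros(20))

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_recovers_template(self, seed):
        rng = np.random.default_rng(seed)
        n_active = int(rng.integers(1, 11))
        amps = np.zeros(10)
        amps[:n_active] = rng.uniform(0.05, 1.0, n_active)
        amps[0] = max(amps[0], 0.1)
        phases = rng.uniform(-179.0, 180.0, 10)
        template = HarmonicTemplate(rng.uniform(-1, 3), tuple(amps), tuple(phases))
        period = rng.uniform(0.25, 2.0)
        d = decompose_beat(synthesize_beat(template, period, 1024.0))
        np.testing.assert_allclose(d.amplitudes, amps, atol=1e-6)
        active = amps > 0
        err = wrap_phase_deg(d.phases_deg[active] - phases[active])
        assert np.max(np.abs(err)) < 1e-3

    def test_ten_harmonics_explain_noise_free_beat(self):
        """Reconstruction from dc + 10 harmonics captures >= 99.9 % of variance."""
        template = _template([1.0, 0.4, 0.2, 0.1], [10.0, -40.0, 100.0, 170.0], dc=2.0)
        beat = synthesize_beat(template, 0.8, 1024.0)
        d = decompose_beat(beat)
        n = beat.size
        t = np.arange(n) / n
        recon = d.dc + sum(
            a * np.cos(2 * np.pi * (k + 1) * t + np.deg2rad(p))
            for k, (a, p) in enumerate(zip(d.amplitudes, d.phases_deg))
        )
        ss_res = np.sum((beat - recon) ** 2)
        ss_tot = np.sum((beat - beat.mean()) ** 2)
        assert 1.0 - ss_res / ss_tot >= 0.999

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance_of_proportions_and_phases(self, c):
        beat = synthesize_beat(_template([1.0, 0.5, 0.2], [0.0, 30.0, 60.0], dc=1.0), 0.8, 1024.0)
        d1, d2 = decompose_beat(beat), decompose_beat(c * beat)
        np.testing.assert_allclose(
            amplitude_proportions(d1), amplitude_proportions(d2), atol=1e-9
        )
        # phases of the active harmonics only; zero harmonics carry no phase
        np.testing.assert_allclose(d1.phases_deg[:3], d2.phases_deg[:3], atol=1e-6)


class TestAmplitudeProportions:
    def test_two_equal_harmonics(self):
        c = amplitude_proportions(_decomp([1, 1] + [0] * 8))
        np.testing.assert_allclose(c, [0.5, 0.5] + [0] * 8)

    def test_weighted_example(self):
        c = amplitude_proportions(_decomp([2, 1, 1] + [0] * 7))
        np.testing.assert_allclose(c, [0.5, 0.25, 0.25] + [0] * 7)

    def test_sums_to_one(self):
        rng = np.random.default_rng(0)
        c = amplitude_proportions(_decomp(rng.uniform(0.1, 2.0, 10)))
        assert c.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(c >= 0)

    def test_first_harmonic_normalization(self):
        c = amplitude_proportions(_decomp([2, 1, 1] + [0] * 7), normalization="first")
        np.testing.assert_allclose(c, [1.0, 0.5, 0.5] + [0] * 7)

    def test_all_zero_rejected(self):
        with pytest.raises(UndefinedFeatureError):
            amplitude_proportions(_decomp([0.0] * 10))


class TestPhaseAngles:
    def test_round_trip_phase(self):
        beat = synthesize_beat(_template([1.0, 0.5, 0.2], [0.0, 30.0, 60.0]), 0.8, 1024.0)
        p = phase_angles(decompose_beat(beat))
        assert p[2] == pytest.approx(60.0, abs=1e-3)

    def test_zero_amplitude_harmonic_is_nan(self):
        p = phase_angles(_decomp([1, 0, 1] + [0] * 7, phases=[10.0] * 10))
        assert np.isnan(p[1])
        assert p[0] == pytest.approx(10.0)

    def test_time_shift_theorem(self):
        """Shifting a beat by d shifts P_n by -n*360*d/period (mod 360)."""
        beat = synthesize_beat(_template([1.0, 0.5, 0.2, 0.1], [0.0, 30.0, 60.0, -90.0]), 0.8, 1024.0)
        n = beat.size
        shift = 57
        p0 = phase_angles(decompose_beat(beat))[:4]
        p1 = phase_angles(decompose_beat(np.roll(beat, shift)))[:4]
        harmonics = np.arange(1, 5)
        expected = wrap_phase_deg(p0 - harmonics * 360.0 * shift / n)
        np.testing.assert_allclose(wrap_phase_deg(p1 - expected), 0.0, atol=1e-6)


class TestWindowedVariability:
    def test_constant_series_has_zero_cv_and_sd(self):
        assert windowed_variability(np.full(10, 0.3), "cv")[0] == pytest.approx(0.0)
        assert windowed_variability(np.full(10, 42.0), "sd")[0] == pytest.approx(0.0)

    def test_hand_computed_cv(self):
        # mean 2, sample SD 1 -> CV = 50 %
        cv = windowed_variability(np.array([1.0, 2.0, 3.0]), "cv")
        np.testing.assert_allclose(cv, 50.0)

    def test_phase_sd_unwraps_across_seam(self):
        # phases hugging +/-180: linear SD would be huge, circular SD is small
        series = np.array([179.0, -179.0, 179.5, -178.5, 179.0])
        sd = windowed_variability(series, "sd")[0]
        assert sd < 5.0

    def test_sliding_window(self):
        series = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        out = windowed_variability(series, "cv", window=3)
        np.testing.assert_allclose(out[1], 100.0 * np.std([1, 2, 3], ddof=1) / 2.0)

    def test_single_beat_is_undefined(self):
        assert np.isnan(windowed_variability(np.array([1.0]), "cv")).all()


class TestBuildFeatureTable:
    def test_schema(self, mini_features):
        assert list(mini_features.columns) == ["subject", "regime", "beat_index", "label"] + FEATURE_COLUMNS
        assert len(FEATURE_COLUMNS) == 40
        assert set(mini_features["label"]) <= {"high", "low"}

    def test_amplitude_proportions_sum_to_one(self, mini_features):
        c_cols = [f"C{n}" for n in range(1, 11)]
        np.testing.assert_allclose(mini_features[c_cols].sum(axis=1), 1.0, atol=1e-9)

    def test_variability_indices_non_negative(self, mini_features):
        cols = [c for c in FEATURE_COLUMNS if c.startswith("CV") or c.endswith("_SD")]
        assert (mini_features[cols] >= 0).all().all()

    def test_higher_regime_has_larger_variability(self, mini_features):
        """The unstable-contact regime inflates CV_n and P_n_SD."""
        grouped = mini_features.groupby("regime")[["CV1", "CV4", "P1_SD", "P5_SD"]].mean()
        assert (grouped.loc["higher"] > grouped.loc["appropriate"]).all()

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            build_feature_table([])
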