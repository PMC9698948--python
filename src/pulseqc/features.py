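"""Per-beat harmonic indices of the pulse waveform.

For each beat, frequency-domain analysis yields the cosine-series
coefficients of the first ten harmonics of the beat's own fundamental
(1/period).  From these, forty indices are computed per beat:

* ``C1..C10``   amplitude proportions: a_n normalized by the total harmonic
  amplitude (or by a1, behind a switch);
* ``CV1..CV10`` beat-to-beat coefficients of variation of C_n, in percent;
* ``P1..P10``   phase angles in degrees, wrapped to (-180, 180];
* ``P1_SD..P10_SD`` beat-to-beat standard deviations of P_n, in degrees,
  computed on the unwrapped phase sequence.

The variability indices need a window of beats; by default the window is the
whole record, so every beat of a record shares the record-level CV_n and
P_n_SD.  A centered sliding window of ``w`` beats is also supported.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segment import BeatSegment, detect_beat_onsets, segment_beats
from .synth import N_HARMONICS, wrap_phase_deg

__all__ = [
    "HarmonicDecomposition",
    "UndefinedFeatureError",
    "decompose_beat",
    "amplitude_proportions",
    "phase_angles",
    "windowed_variability",
    "build_feature_table",
    "FEATURE_COLUMNS",
    "META_COLUMNS",
]

logger = logging.getLogger(__name__)

C_COLUMNS = [f"C{n}" for n in range(1, N_HARMONICS + 1)]
CV_COLUMNS = [f"CV{n}" for n in range(1, N_HARMONICS + 1)]
P_COLUMNS = [f"P{n}" for n in range(1, N_HARMONICS + 1)]
PSD_COLUMNS = [f"P{n}_SD" for n in range(1, N_HARMONICS + 1)]
FEATURE_COLUMNS = C_COLUMNS + CV_COLUMNS + P_COLUMNS + PSD_COLUMNS
META_COLUMNS = ["subject", "regime", "beat_index", "label"]


class UndefinedFeatureError(ValueError):
    """A feature is mathematically undefined for this beat (e.g. zero amplitude)."""


@dataclass(frozen=True)
class HarmonicDecomposition:
    """DC level plus amplitudes a1..a10 and phases phi1..phi10 of one beat."""

    dc: float
    amplitudes: np.ndarray
    phases_deg: np.ndarray


def decompose_beat(beat, n_harmonics=N_HARMONICS) -> HarmonicDecomposition:
    """Project one beat onto cosines of its own fundamental.

    The beat interval defines the fundamental frequency (1/period), so the
    harmonics sit exactly on rFFT bins; the returned coefficients satisfy
    x(t) ~= dc + sum_n a_n cos(2 pi n t / period + phi_n) with phases in
    degrees wrapped to (-180, 180].
    """
    x = beat.samples if isinstance(beat, BeatSegment) else np.asarray(beat, dtype=float)
    n = x.size
    if n < 2 * n_harmonics + 1:
        raise ValueError(f"beat must have at least {2 * n_harmonics + 1} samples")
    spectrum = np.fft.rfft(x)
    dc = spectrum[0].real / n
    coeffs = spectrum[1 : n_harmonics + 1]
    amplitudes = 2.0 * np.abs(coeffs) / n
    phases = wrap_phase_deg(np.degrees(np.angle(coeffs)))
    return HarmonicDecomposition(float(dc), amplitudes, np.atleast_1d(phases))


def amplitude_proportions(decomposition, normalization="sum") -> np.ndarray:
    """Amplitude proportions C_n.

    ``normalization="sum"`` (default): C_n = a_n / sum_k a_k, so the C_n are
    fractions of the total harmonic amplitude and sum to one.
    ``normalization="first"``: C_n = a_n / a1.
    """
    a = decomposition.amplitudes
    if normalization == "sum":
        total = a.sum()
        if total <= 0:
            raise UndefinedFeatureError("all harmonic amplitudes are zero")
        return a / total
    if normalization == "first":
        if a[0] <= 0:
            raise UndefinedFeatureError("fundamental amplitude is zero")
        return a / a[0]
    raise ValueError("normalization must be 'sum' or 'first'")


def phase_angles(decomposition, rel_tol=1e-9) -> np.ndarray:
    """Phase angles P_n in degrees; NaN where the harmonic amplitude vanishes.

    The phase of a (numerically) zero-amplitude harmonic carries no
    information; such entries are flagged NaN and the beat is later excluded
    from P_n statistics.
    """
    a = decomposition.amplitudes
    scale = a.max()
    if scale <= 0:
        raise UndefinedFeatureError("all harmonic amplitudes are zero")
    p = decomposition.phases_deg.astype(float).copy()
    p[a < rel_tol * scale] = np.nan
    return p


def _window_stat(values, kind):
    """Sample statistic over one window; NaN entries ignored; NaN if < 2 values."""
    v = values[~np.isnan(values)]
    if v.size < 2:
        return np.nan
    if kind == "cv":
        mean = v.mean()
        if mean == 0:
            return np.nan
        return 100.0 * v.std(ddof=1) / mean
    if kind == "sd":
        return float(np.unwrap(v, period=360.0).std(ddof=1))
    raise ValueError("kind must be 'cv' or 'sd'")


def windowed_variability(values, kind, window="record") -> np.ndarray:
    """Per-beat variability of a per-beat index series.

    Parameters
    ----------
    values : array, shape (n_beats,) or (n_beats, k)
        Per-beat C_n (for ``kind="cv"``) or P_n (for ``kind="sd"``) series of
        one record.
    kind : {"cv", "sd"}
        ``cv``: 100 * sample SD / mean.  ``sd``: sample SD of the unwrapped
        phase sequence (avoids the +/-180 degree seam).
    window : "record" or odd int
        ``"record"`` assigns the whole-record statistic to every beat;
        an integer gives a centered sliding window of that many beats.

    Windows containing fewer than two defined values yield NaN.
    """
    v = np.asarray(values, dtype=float)
    squeeze = v.ndim == 1
    if squeeze:
        v = v[:, None]
    n_beats, k = v.shape
    out = np.full_like(v, np.nan)
    if n_beats >= 2:
        for j in range(k):
            col = v[:, j]
            if window == "record":
                out[:, j] = _window_stat(col, kind)
            else:
                w = int(window)
                if w < 2:
                    raise ValueError("sliding window must span at least 2 beats")
                half = w // 2
                for i in range(n_beats):
                    lo, hi = max(0, i - half), min(n_beats, i + half + 1)
                    out[i, j] = _window_stat(col[lo:hi], kind)
    return out[:, 0] if squeeze else out


def _beat_labels(record, segments, annotations, tol_samples):
    """Quality label per segment, matched to truth/annotation onsets.

    A segment inherits the label of the nearest annotated onset within
    ``tol_samples``; unmatched segments get ``None`` and are dropped.
    Records with no truth and no annotation are labelled "unlabelled".
    """
    if annotations is not None and (record.subject_id, record.regime) in annotations:
        truth_onsets, truth_labels = annotations[(record.subject_id, record.regime)]
        truth_onsets = np.asarray(truth_onsets, dtype=int)
        truth_labels = np.asarray(truth_labels)
    elif record.truth_onsets is not None and record.truth_beat_labels is not None:
        truth_onsets, truth_labels = record.truth_onsets, record.truth_beat_labels
    else:
        return ["unlabelled"] * len(segments)

    labels = []
    for seg in segments:
        pos = np.searchsorted(truth_onsets, seg.onset)
        best, dist = None, tol_samples + 1
        for cand in (pos - 1, pos):
            if 0 <= cand < truth_onsets.size:
                d = abs(int(truth_onsets[cand]) - seg.onset)
                if d < dist:
                    best, dist = cand, d
        labels.append(str(truth_labels[best]) if dist <= tol_samples else None)
    return labels


def build_feature_table(
    records,
    annotations=None,
    window="record",
    normalization="sum",
    min_hr=30.0,
    max_hr=240.0,
    match_tol=0.025,
) -> pd.DataFrame:
    """Segment every record and assemble the 40-feature beat table.

    Returns one row per retained beat with columns
    ``subject regime beat_index label C1..C10 CV1..CV10 P1..P10 P1_SD..P10_SD``.
    Beats with any undefined feature, and beats that cannot be matched to a
    truth/annotation label within ``match_tol`` seconds, are dropped and
    counted in the log.
    """
    records = list(records)
    if not records:
        raise ValueError("empty cohort")

    rows = []
    dropped = 0
    for record in records:
        onsets = detect_beat_onsets(record, min_hr=min_hr, max_hr=max_hr)
        segments = segment_beats(record, onsets)
        if len(segments) < 2:
            logger.warning(
                "record %s/%s yielded %d beat(s); skipped",
                record.subject_id,
                record.regime,
                len(segments),
            )
            continue
        n = len(segments)
        C = np.full((n, N_HARMONICS), np.nan)
        P = np.full((n, N_HARMONICS), np.nan)
        for k, seg in enumerate(segments):
            dec = decompose_beat(seg)
            try:
                C[k] = amplitude_proportions(dec, normalization=normalization)
            except UndefinedFeatureError:
                pass
            try:
                P[k] = phase_angles(dec)
            except UndefinedFeatureError:
                pass
        CV = windowed_variability(C, "cv", window=window)
        PSD = windowed_variability(P, "sd", window=window)
        labels = _beat_labels(record, segments, annotations, int(round(match_tol * record.sampling_rate)))

        for k, seg in enumerate(segments):
            feats = np.concatenate([C[k], CV[k], P[k], PSD[k]])
            if labels[k] is None or np.isnan(feats).any():
                dropped += 1
                continue
            rows.append([record.subject_id, record.regime, seg.beat_index, labels[k], *feats])

    if not rows:
        raise ValueError("no usable beats in the cohort")
    if dropped:
        logger.info("dropped %d beat(s) with undefined features or unmatched labels", dropped)
    return pd.DataFrame(rows, columns=META_COLUMNS + FEATURE_COLUMNS)
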