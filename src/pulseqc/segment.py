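"""Beat-onset (pulse-foot) detection and beat segmentation.

The detector is a slope-threshold upstroke finder: samples whose first
difference exceeds ``slope_k`` times the record-level robust SD of the
derivative mark systolic upstrokes; each accepted upstroke is traced
backwards to the preceding local minimum, which is taken as the pulse foot.
A refractory period of ``60 / max_hr`` seconds suppresses double triggers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["BeatSegment", "detect_beat_onsets", "segment_beats"]

logger = logging.getLogger(__name__)

#: physiologic beat-period gate, seconds (heart rates 30-240 beats/min)
MIN_PERIOD_S = 0.25
MAX_PERIOD_S = 2.0


@dataclass
class BeatSegment:
    """One beat cut from a record: the half-open interval [onset, end)."""

    subject_id: str
    beat_index: int
    onset: int
    end: int
    samples: np.ndarray
    period: float
    sampling_rate: float

    def __post_init__(self):
        if self.onset >= self.end:
            raise ValueError("onset must precede end")


def detect_beat_onsets(record, min_hr=30.0, max_hr=240.0, slope_k=2.0) -> np.ndarray:
    """Locate pulse feet in a continuous recording.

    Returns strictly increasing sample indices; each onset is the local
    minimum preceding a detected systolic upstroke.  A flat or upstroke-free
    signal yields an empty result with a warning rather than an exception.
    """
    x = np.asarray(record.samples, dtype=float)
    fs = record.sampling_rate
    if x.size < 2 * fs:
        raise ValueError("record must be at least 2 s long")
    if min_hr >= max_hr:
        raise ValueError("min_hr must be smaller than max_hr")

    dx = np.diff(x)
    robust_sd = 1.4826 * np.median(np.abs(dx - np.median(dx)))
    if robust_sd <= 0:
        # mostly-flat signal: the MAD collapses; fall back to the plain SD
        robust_sd = float(dx.std())
    if robust_sd <= 0:
        warnings.warn("flat or near-flat signal: no beats detected")
        return np.empty(0, dtype=int)
    above = dx > slope_k * robust_sd
    if not above.any():
        warnings.warn("no systolic upstrokes found")
        return np.empty(0, dtype=int)

    run_starts = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    refractory = int(round(60.0 / max_hr * fs))

    onsets = []
    last_upstroke = -np.inf
    for s in run_starts:
        if s - last_upstroke < refractory:
            continue
        i = int(s)
        while i > 0 and x[i - 1] < x[i]:  # strict: stop at plateaus and local minima
            i -= 1
        last_upstroke = s
        if onsets and i - onsets[-1] < refractory:
            continue
        onsets.append(i)
    return np.asarray(onsets, dtype=int)


def segment_beats(record, onsets, min_period=MIN_PERIOD_S, max_period=MAX_PERIOD_S) -> list:
    """Cut a record into single-beat segments between consecutive onsets.

    Partial beats before the first and after the last onset are discarded.
    Segments whose implied period falls outside the physiologic gate
    (default 0.25-2.0 s) are dropped and counted in the log.
    """
    onsets = np.asarray(onsets, dtype=int)
    if onsets.size < 2:
        warnings.warn("fewer than two onsets: nothing to segment")
        return []
    fs = record.sampling_rate
    segments = []
    dropped = 0
    index = 0
    for a, b in zip(onsets[:-1], onsets[1:]):
        period = (b - a) / fs
        if not (min_period < period < max_period):
            dropped += 1
            continue
        segments.append(
            BeatSegment(
                subject_id=record.subject_id,
                beat_index=index,
                onset=int(a),
                end=int(b),
                samples=record.samples[a:b],
                period=period,
                sampling_rate=fs,
            )
        )
        index += 1
    if dropped:
        logger.info(
            "dropped %d segment(s) outside the %.2f-%.2f s period gate", dropped, min_period, max_period
        )
    return segments
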