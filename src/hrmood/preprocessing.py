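"""Session segmentation and neutral-baseline normalization.

Each recorded session concatenates a neutral video segment and a target-emotion
video segment. The mean heart rate of the neutral segment is the subject's
baseline; subtracting it from the target segment removes the (large)
between-subject differences in resting heart rate and leaves the
emotion-driven deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError
from .io_formats import HeartRateSeries, SessionRecord

#: Segments shorter than this carry no usable run/difference structure.
MIN_SEGMENT_SAMPLES = 10


@dataclass(frozen=True)
class SegmentedSession:
    """A session split into its neutral and target segments.

    ``baseline_bpm`` is the arithmetic mean of the neutral segment.
    """

    subject_id: str
    emotion: str
    neutral_segment: HeartRateSeries
    target_segment: HeartRateSeries
    baseline_bpm: float


@dataclass(frozen=True)
class NormalizedSeries:
    """Baseline-subtracted target-segment signal (values may be negative)."""

    values: np.ndarray
    dt_s: float

    def __len__(self) -> int:
        return int(np.asarray(self.values).size)


def segment_session(record: SessionRecord) -> SegmentedSession:
    """Split a session at the neutral/target boundary.

    Segments are half-open in time: the neutral segment covers
    ``[0, neutral_duration_s)`` and the target segment
    ``[neutral_duration_s, neutral_duration_s + target_duration_s)``, so the
    boundary sample belongs to the target segment and segment lengths sum to
    the session length.
    """
    series = record.series
    dt = series.dt_s
    n_neutral = int(round(record.neutral_duration_s / dt))
    n_target = int(round(record.target_duration_s / dt))
    n_target = min(n_target, len(series) - n_neutral)
    if n_neutral < MIN_SEGMENT_SAMPLES or n_target < MIN_SEGMENT_SAMPLES:
        raise InsufficientDataError(
            f"session {record.subject_id}/{record.emotion}: segments of "
            f"{n_neutral} and {n_target} samples; need >= {MIN_SEGMENT_SAMPLES} each"
        )
    neutral = HeartRateSeries(
        values=series.values[:n_neutral], dt_s=dt, start_time_s=0.0
    )
    target = HeartRateSeries(
        values=series.values[n_neutral : n_neutral + n_target],
        dt_s=dt,
        start_time_s=0.0,
    )
    return SegmentedSession(
        subject_id=record.subject_id,
        emotion=record.emotion,
        neutral_segment=neutral,
        target_segment=target,
        baseline_bpm=compute_baseline(neutral),
    )


def compute_baseline(neutral: HeartRateSeries) -> float:
    """Arithmetic mean of the neutral segment, in BPM."""
    return float(np.mean(neutral.values))


def normalize_target(target: HeartRateSeries, baseline: float) -> NormalizedSeries:
    """Subtract the neutral baseline from every target sample."""
    return NormalizedSeries(values=target.values - baseline, dt_s=target.dt_s)


def normalize_session(seg: SegmentedSession) -> NormalizedSeries:
    """Convenience wrapper: normalized target signal of a segmented session."""
    return normalize_target(seg.target_segment, seg.baseline_bpm)
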