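"""The 53-feature summary of one 'neutral + target' heart-rate session.

Twenty-two features come from the original (un-normalized) target segment and
thirty-one from the baseline-normalized signal. Many are statistics of
*runs* — maximal stretches over which the signal rises (up), falls (down) or
stays constant (flat): run durations summarize how long the heart rate keeps
moving one way, run amplitudes how far it moves, and their ratio the slope.
Flat runs exist because wrist devices report integer BPM, producing plateaus.

Conventions (documented here because the defining formulas leave them open):

* Mean-of-difference features (first/second order, original and normalized)
  average *absolute* differences by default (``config.diff_absolute``);
  signed sums telescope to near-trivial endpoint differences.
* The second-order difference is the two-step increment ``x[n+2] - x[n]``.
* The root-mean-square of adjacent differences divides by the number of
  differences, N - 1.
* Entropy is the Shannon entropy of the empirical distribution of distinct
  integer-rounded BPM values, in bits by default; 0·log 0 := 0.
* Down-run slopes and amplitudes are reported as positive magnitudes.
* Summary statistics of empty run collections are all 0 (fixed-length
  vectors need a sentinel; a monotone series simply has no down-runs).
* "std" is the population standard deviation (divisor n) everywhere except
  the normalized-signal variance feature, which is the unbiased sample
  variance (divisor N - 1).
* The moving average uses a "valid" window: output length N - window + 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ShapeError
from .io_formats import EMOTIONS, HeartRateSeries, PipelineConfig
from .preprocessing import (
    MIN_SEGMENT_SAMPLES,
    NormalizedSeries,
    SegmentedSession,
    normalize_session,
)

_STATS_MMMMS = ("max", "min", "median", "mean", "std")
_STATS_DIFF = ("max", "min", "std", "median", "mean")

#: Canonical names of the 22 original-signal features, in frozen order.
ORIGINAL_FEATURE_NAMES: tuple[str, ...] = (
    "rate_diff1_mean",
    "rate_diff2_mean",
    "rate_range",
    "rate_data_entropy",
    "max_ratio",
    "min_ratio",
    "rate_adjacent_data_root_mean",
    *(f"rate_down_time_{s}" for s in _STATS_MMMMS),
    *(f"rate_up_time_{s}" for s in _STATS_MMMMS),
    *(f"rate_time_continue_{s}" for s in _STATS_MMMMS),
)

#: Canonical names of the 31 normalized-signal features, in frozen order.
#: Note the up-amplitude group has no "min" member: four statistics only.
NORMALIZED_FEATURE_NAMES: tuple[str, ...] = (
    *(f"rate_down_slope_{s}" for s in _STATS_MMMMS),
    *(f"rate_up_amplitude_{s}" for s in ("max", "median", "mean", "std")),
    *(f"rate_down_amplitude_{s}" for s in _STATS_MMMMS),
    *(f"25_mean_{s}" for s in _STATS_MMMMS),
    "rate_data_mean",
    "rate_data_var",
    *(f"rate_data_normalized_diff1_{s}" for s in _STATS_DIFF),
    *(f"rate_data_normalized_diff2_{s}" for s in _STATS_DIFF),
)

#: The full frozen 53-name feature order: original groups then normalized.
FEATURE_NAMES: tuple[str, ...] = ORIGINAL_FEATURE_NAMES + NORMALIZED_FEATURE_NAMES

assert len(FEATURE_NAMES) == 53

#: Features that summarize the mean level of the normalized signal
#: (the family expected to dominate mutual-information rankings when the
#: emotions differ by a mean heart-rate shift).
NORMALIZED_MEAN_FAMILY: tuple[str, ...] = (
    "rate_data_mean",
    *(f"25_mean_{s}" for s in _STATS_MMMMS),
)


@dataclass(frozen=True)
class Run:
    """A maximal monotone stretch of the signal.

    Consecutive runs share their boundary sample: a run covers samples
    ``start_idx..end_idx`` inclusive, so every run spans at least two samples
    and run durations tile the series, summing to ``(N - 1) * dt_s``.
    """

    direction: str  # "up" | "down" | "flat"
    start_idx: int
    end_idx: int
    duration_s: float
    amplitude: float


def detect_runs(values: Sequence[float], dt_s: float = 1.0) -> list[Run]:
    """Partition a series into maximal up/down/flat runs.

    Consecutive sample-pair differences are classified by sign; each maximal
    stretch of equal sign becomes one run.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("run detection needs at least 2 samples")
    signs = np.sign(np.diff(x)).astype(int)
    runs: list[Run] = []
    start = 0
    for i in range(1, len(signs) + 1):
        if i == len(signs) or signs[i] != signs[start]:
            direction = {1: "up", -1: "down", 0: "flat"}[int(signs[start])]
            runs.append(
                Run(
                    direction=direction,
                    start_idx=start,
                    end_idx=i,
                    duration_s=(i - start) * dt_s,
                    amplitude=float(x[i] - x[start]),
                )
            )
            start = i
    return runs


def _five_stats(values: Iterable[float], order: tuple[str, ...]) -> list[float]:
    """Summary statistics of a collection; all zero if the collection is empty.

    std is the population standard deviation; a singleton has std 0.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return [0.0] * len(order)
    stats = {
        "max": float(np.max(arr)),
        "min": float(np.min(arr)),
        "median": float(np.median(arr)),
        "mean": float(np.mean(arr)),
        "std": float(np.std(arr)),
    }
    return [stats[s] for s in order]


def _mean_diff(diffs: np.ndarray, absolute: bool) -> float:
    return float(np.mean(np.abs(diffs) if absolute else diffs))


def signal_entropy(values: np.ndarray, log_base: float = 2.0) -> float:
    """Shannon entropy of the empirical distribution of distinct BPM values.

    Values are rounded to integers before counting (wearables report integer
    BPM; rounding makes the estimator well-defined for real-valued input).
    """
    _, counts = np.unique(np.rint(np.asarray(values, dtype=float)), return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)) / math.log(log_base))


def extract_original_features(
    target: HeartRateSeries, config: PipelineConfig | None = None
) -> dict[str, float]:
    """The 22 original-signal features, keyed by canonical name in order."""
    config = config or PipelineConfig()
    x = target.values
    n = x.size
    if n < MIN_SEGMENT_SAMPLES:
        raise InsufficientDataError(
            f"original-feature extraction needs >= {MIN_SEGMENT_SAMPLES} samples"
        )
    d1 = np.diff(x)
    d2 = x[2:] - x[:-2]
    runs = detect_runs(x, target.dt_s)
    durations = {
        kind: [r.duration_s for r in runs if r.direction == kind]
        for kind in ("down", "up", "flat")
    }
    out: dict[str, float] = {
        "rate_diff1_mean": _mean_diff(d1, config.diff_absolute),
        "rate_diff2_mean": _mean_diff(d2, config.diff_absolute),
        "rate_range": float(np.max(x) - np.min(x)),
        "rate_data_entropy": signal_entropy(x, config.entropy_log_base),
        "max_ratio": float(np.max(x) / n),
        "min_ratio": float(np.min(x) / n),
        "rate_adjacent_data_root_mean": float(np.sqrt(np.mean(d1**2))),
    }
    for kind, prefix in (
        ("down", "rate_down_time"),
        ("up", "rate_up_time"),
        ("flat", "rate_time_continue"),
    ):
        for stat, value in zip(_STATS_MMMMS, _five_stats(durations[kind], _STATS_MMMMS)):
            out[f"{prefix}_{stat}"] = value
    return out


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """'Valid'-mode moving average; output length is N - window + 1."""
    x = np.asarray(values, dtype=float)
    if x.size < window:
        raise InsufficientDataError(
            f"moving average needs >= {window} samples, got {x.size}"
        )
    return np.convolve(x, np.ones(window) / window, mode="valid")


def extract_normalized_features(
    norm: NormalizedSeries, config: PipelineConfig | None = None
) -> dict[str, float]:
    """The 31 normalized-signal features, keyed by canonical name in order."""
    config = config or PipelineConfig()
    x = np.asarray(norm.values, dtype=float)
    n = x.size
    if n < config.moving_avg_window:
        raise InsufficientDataError(
            f"normalized segment of {n} samples shorter than moving-average "
            f"window {config.moving_avg_window}"
        )
    runs = detect_runs(x, norm.dt_s)
    down = [r for r in runs if r.direction == "down"]
    up = [r for r in runs if r.direction == "up"]
    down_slopes = [abs(r.amplitude) / r.duration_s for r in down]
    up_amplitudes = [r.amplitude for r in up]
    down_amplitudes = [abs(r.amplitude) for r in down]
    ma = moving_average(x, config.moving_avg_window)
    d1 = np.diff(x)
    d2 = x[2:] - x[:-2]

    out: dict[str, float] = {}
    for stat, value in zip(_STATS_MMMMS, _five_stats(down_slopes, _STATS_MMMMS)):
        out[f"rate_down_slope_{stat}"] = value
    up_order = ("max", "median", "mean", "std")
    for stat, value in zip(up_order, _five_stats(up_amplitudes, up_order)):
        out[f"rate_up_amplitude_{stat}"] = value
    for stat, value in zip(_STATS_MMMMS, _five_stats(down_amplitudes, _STATS_MMMMS)):
        out[f"rate_down_amplitude_{stat}"] = value
    for stat, value in zip(_STATS_MMMMS, _five_stats(ma, _STATS_MMMMS)):
        out[f"25_mean_{stat}"] = value
    out["rate_data_mean"] = float(np.mean(x))
    out["rate_data_var"] = float(np.var(x, ddof=1))
    for series, prefix in ((d1, "rate_data_normalized_diff1"), (d2, "rate_data_normalized_diff2")):
        for stat, value in zip(_STATS_DIFF, _five_stats(series, _STATS_DIFF)):
            out[f"{prefix}_{stat}"] = value
        # the "mean" member is the mean-of-difference feature, so it follows
        # the diff_absolute convention rather than the signed collection mean
        out[f"{prefix}_mean"] = _mean_diff(series, config.diff_absolute)
    return out


@dataclass(frozen=True)
class FeatureVector:
    """One sample: the ordered 53 feature values of a target-emotion segment."""

    subject_id: str
    emotion: str
    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.names != FEATURE_NAMES:
            raise ShapeError("feature names do not match the canonical order")
        if values.shape != (53,):
            raise ShapeError(f"feature vector must have 53 values, got {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ShapeError("feature vector contains non-finite values")


def extract_features(
    seg: SegmentedSession, config: PipelineConfig | None = None
) -> FeatureVector:
    """Full 53-value feature vector of one segmented session."""
    config = config or PipelineConfig()
    original = extract_original_features(seg.target_segment, config)
    normalized = extract_normalized_features(normalize_session(seg), config)
    merged = {**original, **normalized}
    values = np.array([merged[name] for name in FEATURE_NAMES])
    return FeatureVector(subject_id=seg.subject_id, emotion=seg.emotion, values=values)


@dataclass
class FeatureMatrix:
    """A stack of feature vectors with subject ids and emotion labels."""

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        expected = ["subject_id", "emotion", *FEATURE_NAMES]
        if list(self.frame.columns) != expected:
            raise ShapeError(
                "feature matrix columns do not match 'subject_id,emotion' + "
                "the canonical 53-feature order"
            )
        bad = set(self.frame["emotion"]) - set(EMOTIONS)
        if bad:
            raise ShapeError(f"unknown emotion labels {sorted(bad)}")

    @classmethod
    def from_vectors(cls, vectors: Iterable[FeatureVector]) -> "FeatureMatrix":
        records = [
            {"subject_id": v.subject_id, "emotion": v.emotion,
             **dict(zip(v.names, v.values))}
            for v in vectors
        ]
        if not records:
            raise ShapeError("cannot build a feature matrix from zero vectors")
        return cls(pd.DataFrame.from_records(records)[
            ["subject_id", "emotion", *FEATURE_NAMES]
        ])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureMatrix":
        return cls(frame[["subject_id", "emotion", *FEATURE_NAMES]].copy())

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> np.ndarray:
        """The (n_samples, 53) value block."""
        return self.frame[list(FEATURE_NAMES)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        """Emotion labels, one per row."""
        return self.frame["emotion"].to_numpy()

    @property
    def subjects(self) -> np.ndarray:
        return self.frame["subject_id"].to_numpy()

    def restrict(self, classes: Sequence[str]) -> "FeatureMatrix":
        """Rows whose label is in ``classes`` (order preserved)."""
        mask = self.frame["emotion"].isin(list(classes))
        return FeatureMatrix(self.frame.loc[mask].reset_index(drop=True))


def matrix_from_sessions(
    sessions: Iterable, config: PipelineConfig | None = None,
    skip_errors: bool = False, log=None,
) -> FeatureMatrix:
    """Segment, normalize and featurize a batch of sessions.

    With ``skip_errors`` a failing session is dropped (reported through
    ``log``) instead of aborting the batch; an all-failing batch still raises.
    """
    from .errors import HRMoodError
    from .preprocessing import segment_session

    vectors = []
    for session in sessions:
        try:
            vectors.append(extract_features(segment_session(session), config))
        except HRMoodError as exc:
            if not skip_errors:
                raise
            if log is not None:
                log(f"skipping {session.subject_id}/{session.emotion}: {exc}")
    return FeatureMatrix.from_vectors(vectors)
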