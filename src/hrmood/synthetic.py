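"""Emotion-conditioned heart-rate session simulator.

The study design this emulates: 25 subjects each watch three 'neutral +
target' video pairs (neutral+neutral, neutral+happy, neutral+sad) while a
wrist device records integer BPM once per second. No subject-level recordings
are deposited, so this module generates sessions with the statistical
structure the analysis assumes:

* each subject has a resting baseline drawn from a population distribution;
* within a segment the heart rate follows a mean-reverting AR(1) process
  around the segment's level — slow drifts with small steps;
* the target emotion shifts the level (happiness lowers heart rate relative
  to neutral, sadness raises it, per the physiology literature); sadness
  additionally scales the innovation noise, so happy-vs-sad is not purely a
  mean-shift problem while neutral-vs-happy is;
* values are rounded to integer BPM, which creates the plateaus that the
  flat-run (T_Continue) features measure.

The AR(1)-plus-rounding process is the minimal generator reproducing the
visual structure of real wrist traces; it is a test harness, not a claim
about cardiac physiology. Effect magnitudes are scenario parameters, not
estimates of the original study's (unreported) effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ParameterError
from .features import FeatureMatrix
from .io_formats import (
    EMOTIONS,
    HeartRateSeries,
    Manifest,
    ManifestRow,
    SessionRecord,
    write_manifest,
    write_trace,
)

#: Target-segment mean shift relative to the subject baseline, in BPM.
DEFAULT_MEAN_SHIFT: dict[str, float] = {"neutral": 0.0, "happy": -2.0, "sad": 1.0}

#: Target-segment innovation-noise multiplier per emotion. Only sadness gets
#: a variance increase: neutral-vs-happy stays a pure mean-shift contrast
#: (so normalized-mean features dominate its feature ranking, as the
#: analysis expects), while happy-vs-sad is deliberately not reducible to a
#: mean shift.
DEFAULT_SD_SCALE: dict[str, float] = {"neutral": 1.0, "happy": 1.0, "sad": 1.5}


@dataclass(frozen=True)
class SimulationConfig:
    """Scenario parameters of the synthetic study.

    Defaults reproduce the study design: 25 subjects, one session per
    emotion, neutral segments of 68-122 s and target segments of 53-233 s
    (the stimulus-video duration ranges), integer BPM at 1 sample/s.
    """

    n_subjects: int = 25
    subject_baseline_mean: float = 72.0
    subject_baseline_sd: float = 6.0
    emotion_mean_shift: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MEAN_SHIFT)
    )
    emotion_sd_scale: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SD_SCALE)
    )
    ar_coefficient: float = 0.9
    innovation_sd: float = 0.8
    neutral_duration_range_s: tuple[int, int] = (68, 122)
    target_duration_range_s: tuple[int, int] = (53, 233)
    quantize_integer: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        if not 0 <= self.ar_coefficient < 1:
            raise ParameterError("ar_coefficient must lie in [0, 1)")
        if self.subject_baseline_sd <= 0 or self.innovation_sd <= 0:
            raise ParameterError("standard deviations must be > 0")
        if set(self.emotion_mean_shift) != set(EMOTIONS):
            raise ParameterError(f"emotion_mean_shift must cover {EMOTIONS}")
        if set(self.emotion_sd_scale) != set(EMOTIONS):
            raise ParameterError(f"emotion_sd_scale must cover {EMOTIONS}")
        if any(s <= 0 for s in self.emotion_sd_scale.values()):
            raise ParameterError("emotion_sd_scale values must be > 0")
        for lo, hi in (self.neutral_duration_range_s, self.target_duration_range_s):
            if not 0 < lo <= hi:
                raise ParameterError("duration ranges must satisfy 0 < lo <= hi")


def _ar1(
    rng: np.random.Generator,
    n: int,
    mean: float,
    phi: float,
    innovation_sd: float,
    x0: float,
) -> np.ndarray:
    """Mean-reverting AR(1) path of length n started at x0 (x0 excluded)."""
    shocks = rng.normal(0.0, innovation_sd, size=n)
    out = np.empty(n)
    prev = x0
    for i in range(n):
        prev = mean + phi * (prev - mean) + shocks[i]
        out[i] = prev
    return out


def simulate_session(
    subject_baseline: float,
    emotion: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    subject_id: str = "S00",
    neutral_duration_s: int | None = None,
    target_duration_s: int | None = None,
) -> SessionRecord:
    """Generate one 'neutral + target' session for a subject.

    The neutral segment starts at the AR(1) stationary distribution around
    the subject baseline; the target segment continues from the last neutral
    sample while reverting to the emotion-shifted level, so the trace is
    continuous across the cut as in real recordings.
    """
    if emotion not in EMOTIONS:
        raise ParameterError(f"unknown emotion {emotion!r}")
    lo_n, hi_n = config.neutral_duration_range_s
    lo_t, hi_t = config.target_duration_range_s
    if neutral_duration_s is None:
        neutral_duration_s = int(rng.integers(lo_n, hi_n + 1))
    if target_duration_s is None:
        target_duration_s = int(rng.integers(lo_t, hi_t + 1))
    phi = config.ar_coefficient
    stationary_sd = config.innovation_sd / np.sqrt(1.0 - phi**2)
    x0 = rng.normal(subject_baseline, stationary_sd)
    neutral = _ar1(
        rng, neutral_duration_s, subject_baseline, phi, config.innovation_sd, x0
    )
    target_mean = subject_baseline + config.emotion_mean_shift[emotion]
    target = _ar1(
        rng,
        target_duration_s,
        target_mean,
        phi,
        config.innovation_sd * config.emotion_sd_scale[emotion],
        neutral[-1],
    )
    values = np.concatenate([neutral, target])
    if config.quantize_integer:
        values = np.rint(values)
    values = np.clip(values, 30.0, 220.0)  # keep pathological configs in range
    return SessionRecord(
        subject_id=subject_id,
        emotion=emotion,
        neutral_duration_s=float(neutral_duration_s),
        target_duration_s=float(target_duration_s),
        series=HeartRateSeries(values=values, dt_s=1.0, start_time_s=0.0),
    )


def simulate_study(config: SimulationConfig | None = None) -> list[SessionRecord]:
    """Generate the full study: n_subjects x 3 sessions, deterministic in seed."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    sessions: list[SessionRecord] = []
    for s in range(config.n_subjects):
        subject_id = f"S{s + 1:02d}"
        baseline = rng.normal(config.subject_baseline_mean, config.subject_baseline_sd)
        for emotion in EMOTIONS:
            sessions.append(
                simulate_session(baseline, emotion, config, rng, subject_id)
            )
    return sessions


def write_study(sessions: Sequence[SessionRecord], out_dir: str | Path) -> Manifest:
    """Write trace CSVs plus manifest for a simulated study; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for session in sessions:
        name = f"{session.subject_id}_{session.emotion}.csv"
        write_trace(session.series, out_dir / name)
        rows.append(
            ManifestRow(
                subject_id=session.subject_id,
                emotion=session.emotion,
                neutral_duration_s=session.neutral_duration_s,
                target_duration_s=session.target_duration_s,
                trace_path=out_dir / name,
            )
        )
    manifest = Manifest(rows=tuple(rows))
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def recover_planted_effect(
    matrix: FeatureMatrix, config: SimulationConfig
) -> dict[str, float]:
    """Estimate the planted emotion mean shifts from the data_mean feature.

    The normalized-mean feature of a target segment estimates the segment's
    level shift relative to the subject's neutral baseline, so the
    across-subject mean of ``rate_data_mean`` per emotion (relative to the
    neutral sessions) recovers the planted shift. Reports the estimated gap
    and its bias against the scenario value for happy and sad.
    """
    frame = matrix.to_frame()
    per_emotion = frame.groupby("emotion")["rate_data_mean"].mean()
    neutral_level = float(per_emotion.get("neutral", 0.0))
    report: dict[str, float] = {"neutral_data_mean": neutral_level}
    for emotion in ("happy", "sad"):
        estimate = float(per_emotion.get(emotion, np.nan)) - neutral_level
        planted = float(config.emotion_mean_shift[emotion])
        report[f"{emotion}_gap_estimate_bpm"] = estimate
        report[f"{emotion}_gap_planted_bpm"] = planted
        report[f"{emotion}_gap_bias_bpm"] = estimate - planted
    return report
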