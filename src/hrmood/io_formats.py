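"""On-disk dialects and core domain types for wearable heart-rate sessions.

All files are plain delimited text:

* trace CSV — header ``time_s,hr_bpm``, one row per sample on a uniform grid;
* manifest CSV — header
  ``subject_id,emotion,neutral_duration_s,target_duration_s,trace_path``,
  trace paths resolved relative to the manifest file;
* feature-matrix CSV — ``subject_id,emotion`` followed by the 53 canonical
  feature columns, written with enough digits to round-trip losslessly;
* pipeline config — a flat YAML mapping; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import (
    DuplicateRecordError,
    FormatError,
    InsufficientDataError,
    ParameterError,
    VocabularyError,
)

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .features import FeatureMatrix

#: Emotion vocabulary; the order is canonical (used for confusion matrices).
EMOTIONS: tuple[str, ...] = ("neutral", "happy", "sad")

#: Heart-rate plausibility bounds in beats per minute (exclusive).
BPM_MIN = 20.0
BPM_MAX = 250.0

#: Default k grid for top-k feature selection.
DEFAULT_K_GRID: tuple[int, ...] = (20, 16, 12, 10, 8, 5)

_TRACE_COLUMNS = ("time_s", "hr_bpm")
_MANIFEST_COLUMNS = (
    "subject_id",
    "emotion",
    "neutral_duration_s",
    "target_duration_s",
    "trace_path",
)


@dataclass(frozen=True)
class HeartRateSeries:
    """A uniformly sampled heart-rate trace.

    Parameters
    ----------
    values : ndarray
        BPM samples; integer-valued reals in the open interval (20, 250).
    dt_s : float
        Sampling interval in seconds. The canonical rate is 1 sample/s but
        other uniform rates are carried explicitly.
    start_time_s : float
        Time offset of the first sample, in seconds.
    """

    values: np.ndarray
    dt_s: float = 1.0
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise InsufficientDataError(
                f"heart-rate series needs at least 2 samples, got {values.size}"
            )
        if not np.all((values > BPM_MIN) & (values < BPM_MAX)):
            bad = values[(values <= BPM_MIN) | (values >= BPM_MAX)]
            raise FormatError(f"BPM values outside ({BPM_MIN}, {BPM_MAX}): {bad[:5]}")
        if not self.dt_s > 0:
            raise ParameterError(f"dt_s must be > 0, got {self.dt_s}")
        if self.start_time_s < 0:
            raise ParameterError(f"start_time_s must be >= 0, got {self.start_time_s}")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds: ``start_time_s + i * dt_s``."""
        return self.start_time_s + self.dt_s * np.arange(len(self))

    @property
    def duration_s(self) -> float:
        """Time span covered by the samples, ``(N - 1) * dt_s``."""
        return (len(self) - 1) * self.dt_s


@dataclass(frozen=True)
class SessionRecord:
    """One 'neutral + target' pair session.

    The first ``neutral_duration_s`` of the trace were recorded during the
    neutral stimulus; the emotion label refers to the second (target) segment.
    """

    subject_id: str
    emotion: str
    neutral_duration_s: float
    target_duration_s: float
    series: HeartRateSeries

    def __post_init__(self) -> None:
        if self.emotion not in EMOTIONS:
            raise VocabularyError(
                f"unknown emotion {self.emotion!r}; expected one of {EMOTIONS}"
            )
        if self.neutral_duration_s <= 0 or self.target_duration_s <= 0:
            raise ParameterError("segment durations must be positive")
        span = self.series.duration_s + self.series.dt_s
        if self.neutral_duration_s + self.target_duration_s > span + self.series.dt_s:
            raise FormatError(
                "declared durations "
                f"({self.neutral_duration_s} + {self.target_duration_s} s) exceed "
                f"series span ({span} s)"
            )


@dataclass(frozen=True)
class ManifestRow:
    """One manifest line: session metadata plus the path of its trace file."""

    subject_id: str
    emotion: str
    neutral_duration_s: float
    target_duration_s: float
    trace_path: Path


@dataclass(frozen=True)
class Manifest:
    """An ordered collection of session references with unique (subject, emotion)."""

    rows: tuple[ManifestRow, ...]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for row in self.rows:
            key = (row.subject_id, row.emotion)
            if key in seen:
                raise DuplicateRecordError(f"duplicate (subject, emotion) pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[ManifestRow]:
        return iter(self.rows)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the feature/selection/evaluation pipeline.

    ``diff_absolute`` controls whether the four mean-of-difference features
    average absolute or signed differences (signed sums telescope to endpoint
    differences, so absolute is the default). ``entropy_log_base`` selects bits
    (2) or nats (e) for the heart-rate entropy feature.
    """

    diff_absolute: bool = True
    entropy_log_base: float = 2.0
    moving_avg_window: int = 25
    k_grid: tuple[int, ...] = DEFAULT_K_GRID
    n_eval_runs: int = 10
    rng_seed: int = 0
    select_outside_folds: bool = False
    classifier_params: Mapping[str, Mapping[str, object]] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "k_grid", tuple(int(k) for k in self.k_grid))
        if self.moving_avg_window < 2:
            raise ParameterError(
                f"moving_avg_window must be >= 2, got {self.moving_avg_window}"
            )
        if self.entropy_log_base not in (2.0, float(np.e)):
            raise ParameterError("entropy_log_base must be 2 or e")
        for k in self.k_grid:
            if not 1 <= k <= 53:
                raise ParameterError(f"k={k} outside [1, 53]")
        if self.n_eval_runs < 1:
            raise ParameterError("n_eval_runs must be >= 1")


def read_trace(path: str | Path) -> HeartRateSeries:
    """Read a heart-rate trace CSV and infer its sampling interval.

    The interval is the median of consecutive time deltas; a grid whose
    maximum deviation from that median exceeds 10% is rejected as non-uniform.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in _TRACE_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing trace columns {missing}")
    if len(frame) < 2:
        raise InsufficientDataError(f"{path}: trace has {len(frame)} rows, need >= 2")
    times = frame["time_s"].to_numpy(dtype=float)
    deltas = np.diff(times)
    if np.any(deltas <= 0):
        raise FormatError(f"{path}: time_s is not strictly increasing")
    dt = float(np.median(deltas))
    if np.max(np.abs(deltas - dt)) > 0.1 * dt:
        raise FormatError(
            f"{path}: non-uniform time grid (max delta deviation "
            f"{np.max(np.abs(deltas - dt)):.3g} s vs dt {dt:.3g} s)"
        )
    return HeartRateSeries(
        values=frame["hr_bpm"].to_numpy(dtype=float),
        dt_s=dt,
        start_time_s=float(times[0]),
    )


def write_trace(series: HeartRateSeries, path: str | Path) -> None:
    """Write a trace CSV that :func:`read_trace` reproduces exactly."""
    frame = pd.DataFrame({"time_s": series.times, "hr_bpm": series.values})
    frame.to_csv(path, index=False, float_format="%.12g")


def read_manifest(path: str | Path) -> Manifest:
    """Read a session manifest; trace paths resolve relative to the manifest."""
    path = Path(path)
    frame = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in _MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing manifest columns {missing}")
    rows = []
    for rec in frame.itertuples(index=False):
        if rec.emotion not in EMOTIONS:
            raise VocabularyError(
                f"{path}: unknown emotion {rec.emotion!r}; expected one of {EMOTIONS}"
            )
        if rec.neutral_duration_s <= 0 or rec.target_duration_s <= 0:
            raise FormatError(f"{path}: non-positive duration for {rec.subject_id}")
        trace_path = Path(rec.trace_path)
        if not trace_path.is_absolute():
            trace_path = path.parent / trace_path
        rows.append(
            ManifestRow(
                subject_id=str(rec.subject_id),
                emotion=str(rec.emotion),
                neutral_duration_s=float(rec.neutral_duration_s),
                target_duration_s=float(rec.target_duration_s),
                trace_path=trace_path,
            )
        )
    return Manifest(rows=tuple(rows))


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    """Write a manifest CSV with trace paths relative to the manifest file."""
    path = Path(path)
    records = []
    for row in manifest:
        trace = row.trace_path
        try:
            trace = trace.relative_to(path.parent)
        except ValueError:
            pass
        records.append(
            {
                "subject_id": row.subject_id,
                "emotion": row.emotion,
                "neutral_duration_s": row.neutral_duration_s,
                "target_duration_s": row.target_duration_s,
                "trace_path": str(trace),
            }
        )
    pd.DataFrame.from_records(records, columns=list(_MANIFEST_COLUMNS)).to_csv(
        path, index=False, float_format="%.12g"
    )


def load_session(row: ManifestRow) -> SessionRecord:
    """Load the trace behind one manifest row into a full session record."""
    return SessionRecord(
        subject_id=row.subject_id,
        emotion=row.emotion,
        neutral_duration_s=row.neutral_duration_s,
        target_duration_s=row.target_duration_s,
        series=read_trace(row.trace_path),
    )


def write_feature_matrix(matrix: "FeatureMatrix", path: str | Path) -> None:
    """Write a feature matrix CSV (header + one row per sample).

    Values carry 15 significant digits so a read/write round-trip is lossless
    well below the 1e-9 relative test tolerance.
    """
    matrix.to_frame().to_csv(path, index=False, float_format="%.15g")


def read_feature_matrix(path: str | Path) -> "FeatureMatrix":
    """Read a feature matrix CSV written by :func:`write_feature_matrix`."""
    from .features import FeatureMatrix

    frame = pd.read_csv(path, dtype={"subject_id": str})
    return FeatureMatrix.from_frame(frame)


def read_config(path: str | Path) -> PipelineConfig:
    """Read a flat YAML config; any key not in :class:`PipelineConfig` fails."""
    with open(path) as handle:
        data = yaml.safe_load(handle)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ParameterError(f"{path}: unknown config keys {unknown}")
    if "entropy_log_base" in data and data["entropy_log_base"] == "e":
        data["entropy_log_base"] = float(np.e)
    return PipelineConfig(**data)


def write_config(config: PipelineConfig, path: str | Path) -> None:
    """Write a config snapshot as flat YAML (the RunRecord companion file)."""
    data = dataclasses.asdict(config)
    data["k_grid"] = list(config.k_grid)
    if data["classifier_params"] is not None:
        data["classifier_params"] = {
            fam: dict(params) for fam, params in data["classifier_params"].items()
        }
    with open(path, "w") as handle:
        yaml.safe_dump(data, handle, sort_keys=False)
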