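"""Core data model for the ambient-audio phenotyping pipeline.

The pipeline moves through four tabular shapes:

* :class:`RecordingLog` — raw per-recording rows for one subject (one row
  per ~15 s audio sample taken roughly every 5 minutes): local wall-clock
  timestamp, environment volume in arbitrary device units, and a binary
  speech-detected flag.
* :class:`RegularVolumeSeries` — the volume series after resampling onto a
  fixed wall-clock grid, imputation, outlier clipping and 0–1 scaling.
* :class:`SubjectScales` — self-report symptom scales (LSAS, GAD-7, PHQ-8,
  SDS) plus demographics, at intake and exit.
* :class:`FeatureRow` / :class:`CorrelationReport` — the four behavioural
  features per subject and the feature × scale Pearson grid.

Timestamps are *local civil* (wall-clock) time with no zone offset: the
sleep window and day-of-week logic are defined on the clock the subject
lives by.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import RangeError

#: Closed score ranges of the four self-report scales.
SCALE_RANGES: dict[str, tuple[int, int]] = {
    "lsas": (0, 144),
    "gad7": (0, 21),
    "phq8": (0, 24),
    "sds": (0, 30),
}

SCALES = tuple(SCALE_RANGES)
TIMEPOINTS = ("intake", "exit")
SEXES = ("female", "male")

#: Canonical feature column names, in report order.
FEATURES = (
    "daily_similarity",
    "sleep_disturbance_all",
    "sleep_disturbance_weeknights",
    "speech_presence_ratio",
)


@dataclass
class RecordingLog:
    """Raw recording rows for one subject, sorted by timestamp.

    ``timestamps`` is a ``datetime64[s]`` array (strictly increasing),
    ``volumes`` a float array of finite device-unit volumes, and
    ``speech`` a boolean array flagging recordings in which intelligible
    speech was detected.
    """

    subject_id: str
    timestamps: np.ndarray
    volumes: np.ndarray
    speech: np.ndarray

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[s]")
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.speech = np.asarray(self.speech, dtype=bool)
        n = len(self.timestamps)
        if n == 0:
            raise RangeError(f"subject {self.subject_id}: empty recording log")
        if len(self.volumes) != n or len(self.speech) != n:
            raise RangeError(f"subject {self.subject_id}: column length mismatch")
        if not np.all(np.isfinite(self.volumes)):
            raise RangeError(f"subject {self.subject_id}: non-finite volume")
        if n > 1 and not np.all(np.diff(self.timestamps.astype("int64")) > 0):
            raise RangeError(
                f"subject {self.subject_id}: timestamps not strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass(frozen=True)
class SubjectScales:
    """One subject's self-report scores and demographics at one timepoint."""

    subject_id: str
    timepoint: str
    lsas: int
    gad7: int
    phq8: int
    sds: int
    age: float
    sex: str

    def __post_init__(self):
        if self.timepoint not in TIMEPOINTS:
            raise RangeError(
                f"subject {self.subject_id}: timepoint {self.timepoint!r} "
                f"not in {TIMEPOINTS}"
            )
        if self.sex not in SEXES:
            raise RangeError(
                f"subject {self.subject_id}: sex {self.sex!r} not in {SEXES}"
            )
        for scale, (lo, hi) in SCALE_RANGES.items():
            v = getattr(self, scale)
            if not (lo <= v <= hi):
                raise RangeError(
                    f"subject {self.subject_id}: {scale}={v} outside [{lo}, {hi}]"
                )
        if not (0 <= self.age <= 130):
            raise RangeError(f"subject {self.subject_id}: implausible age {self.age}")

    def score(self, scale: str) -> int:
        return getattr(self, scale)


@dataclass(frozen=True)
class RegularVolumeSeries:
    """Volume values on a fixed wall-clock grid for one subject.

    ``grid_start`` lies on a period-minute wall-clock boundary (…:00, :05,
    …) so the 00:00–06:00 sleep window aligns exactly with grid points.
    """

    subject_id: str
    grid_start: np.datetime64
    period_min: int
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        object.__setattr__(self, "grid_start", np.datetime64(self.grid_start, "s"))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.values) < 2:
            raise RangeError(f"subject {self.subject_id}: series shorter than 2")
        if not np.all(np.isfinite(self.values)):
            raise RangeError(f"subject {self.subject_id}: non-finite series value")
        start_s = self.grid_start.astype("int64")
        if start_s % (self.period_min * 60) != 0:
            raise RangeError(
                f"subject {self.subject_id}: grid_start not on a "
                f"{self.period_min}-min boundary"
            )

    def __len__(self) -> int:
        return len(self.values)

    def times(self) -> np.ndarray:
        """Grid timestamps as ``datetime64[s]``."""
        step = np.timedelta64(self.period_min * 60, "s")
        return self.grid_start + np.arange(len(self.values)) * step

    def seconds_of_day(self) -> np.ndarray:
        """Wall-clock seconds since local midnight for each grid point."""
        return self.times().astype("int64") % 86400

    def weekdays(self) -> np.ndarray:
        """Day of week per grid point, Monday=0 … Sunday=6 (civil date)."""
        days = self.times().astype("int64") // 86400
        # 1970-01-01 was a Thursday (weekday 3)
        return (days + 3) % 7


@dataclass
class FeatureRow:
    """The four behavioural features for one subject, plus inclusion metadata.

    A feature that is undefined for the subject (e.g. zero-variance
    autocorrelation segment) is stored as ``None`` and later excluded
    pairwise from correlation cells.
    """

    subject_id: str
    daily_similarity: float | None
    sleep_disturbance_all: float | None
    sleep_disturbance_weeknights: float | None
    speech_presence_ratio: float | None
    n_recordings: int
    included: bool

    def __post_init__(self):
        ds = self.daily_similarity
        if ds is not None and not -1 - 1e-9 <= ds <= 1 + 1e-9:
            raise RangeError(f"subject {self.subject_id}: daily_similarity {ds}")
        for name in ("sleep_disturbance_all", "sleep_disturbance_weeknights"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise RangeError(f"subject {self.subject_id}: {name}={v}")
        spr = self.speech_presence_ratio
        if spr is not None and not 0 <= spr <= 1:
            raise RangeError(
                f"subject {self.subject_id}: speech_presence_ratio {spr}"
            )
        if self.n_recordings < 0:
            raise RangeError(f"subject {self.subject_id}: negative n_recordings")

    def get(self, feature: str) -> float | None:
        return getattr(self, feature)


@dataclass(frozen=True)
class CorrelationCell:
    """One (feature, scale) Pearson cell: r, two-sided p, and pair count.

    ``r`` and ``p`` are ``None`` when the cell is unavailable (fewer than
    3 complete pairs, or a constant input).
    """

    r: float | None
    p: float | None
    n: int


@dataclass
class CorrelationReport:
    """Feature × scale grid of Pearson correlation cells."""

    cells: dict[tuple[str, str], CorrelationCell] = field(default_factory=dict)

    def __getitem__(self, key: tuple[str, str]) -> CorrelationCell:
        return self.cells[key]

    def __setitem__(self, key: tuple[str, str], cell: CorrelationCell):
        feature, scale = key
        if cell.r is not None and abs(cell.r) > 1 + 1e-12:
            raise RangeError(f"cell {feature}/{scale}: |r| > 1")
        self.cells[key] = cell

    def __iter__(self):
        return iter(sorted(self.cells))

    def __len__(self):
        return len(self.cells)


@dataclass(frozen=True)
class SleepWindowSpec:
    """Wall-clock window and night filter for the sleep-disturbance feature.

    Defaults follow the common-sleep-hours convention: 12:00 AM to 6:00 AM
    local time, half-open so a 06:00 grid point is excluded. ``weeknights``
    keeps samples whose own calendar day-of-week is Monday–Friday (so the
    Monday 00:00–06:00 block, the night following Sunday, is included).
    """

    start_hour: float = 0.0
    end_hour: float = 6.0
    day_filter: str = "all_nights"  # or "weeknights"

    def __post_init__(self):
        if not (0 <= self.start_hour < self.end_hour <= 24):
            raise RangeError(
                f"invalid sleep window [{self.start_hour}, {self.end_hour})"
            )
        if self.day_filter not in ("all_nights", "weeknights"):
            raise RangeError(f"unknown day_filter {self.day_filter!r}")


@dataclass(frozen=True)
class ScreeningRule:
    """Inclusive screening cutoff on one scale (score >= cutoff is positive)."""

    scale: str
    cutoff: int

    def __post_init__(self):
        if self.scale not in SCALE_RANGES:
            raise RangeError(f"unknown scale {self.scale!r}")
        lo, hi = SCALE_RANGES[self.scale]
        if not lo <= self.cutoff <= hi:
            raise RangeError(
                f"cutoff {self.cutoff} outside {self.scale} range [{lo}, {hi}]"
            )


#: Literature screening cutoffs: LSAS >= 60 (social anxiety, generalized
#: subtype), GAD-7 >= 10 (generalized anxiety), PHQ-8 >= 10 (depression).
DEFAULT_SCREENING_RULES = (
    ScreeningRule("lsas", 60),
    ScreeningRule("gad7", 10),
    ScreeningRule("phq8", 10),
)


@dataclass(frozen=True)
class GroupTestResult:
    """A two-group test result (Student t or Pearson chi-square)."""

    statistic: float
    df: int
    p: float

    def __post_init__(self):
        if self.df <= 0:
            raise RangeError(f"df must be positive, got {self.df}")
        if not (0 <= self.p <= 1):
            raise RangeError(f"p outside [0, 1]: {self.p}")
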