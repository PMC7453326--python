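"""The four behavioural features extracted from ambient-audio logs.

Three features come from the preprocessed volume series:

* **daily similarity** — the autocorrelation of the series at a 24-hour
  lag (288 samples at a 5-minute period), quantifying how regular the
  subject's daily pattern of activity and inactivity is. Implemented as
  the Pearson correlation between the series and its lag-shifted copy,
  each overlapping segment centred by its own mean.
* **sleep disturbance (all nights / weeknights)** — the sample SD of the
  volume values whose wall-clock time falls in the 00:00–06:00 window,
  pooled across all qualifying nights; a proxy for how noisy the
  subject's environment is during common sleep hours. The weeknights
  variant keeps only samples whose calendar day is Monday–Friday.

The fourth, the **speech presence ratio**, is the proportion of raw
recordings in which speech was detected — computed on the raw log with no
preprocessing, as a context-unaware proxy for social interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FeatureUndefinedError
from .preprocessing import preprocess, sufficiency_filter
from .types import FeatureRow, RecordingLog, RegularVolumeSeries, SleepWindowSpec


def daily_similarity(series: RegularVolumeSeries, lag_hours: float = 24.0) -> float:
    """Autocorrelation of the volume series at a fixed lag (default 24 h).

    Pearson correlation of ``values[:-lag]`` with ``values[lag:]``, each
    segment centred by its own mean. Unaffected by affine rescaling of the
    series. Raises :class:`FeatureUndefinedError` when the series is too
    short (< lag + 2 samples) or either segment has zero variance.
    """
    lag = int(round(lag_hours * 60 / series.period_min))
    v = series.values
    if len(v) < lag + 2:
        raise FeatureUndefinedError(
            f"subject {series.subject_id}: series of {len(v)} samples too short "
            f"for lag {lag}"
        )
    a = v[:-lag]
    b = v[lag:]
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        raise FeatureUndefinedError(
            f"subject {series.subject_id}: zero-variance lag segment"
        )
    return float((a @ b) / denom)


def sleep_window_mask(
    series: RegularVolumeSeries, spec: SleepWindowSpec
) -> np.ndarray:
    """Boolean mask of grid points inside the (half-open) sleep window."""
    sec = series.seconds_of_day()
    mask = (sec >= spec.start_hour * 3600) & (sec < spec.end_hour * 3600)
    if spec.day_filter == "weeknights":
        mask &= series.weekdays() < 5  # Monday=0 .. Friday=4
    return mask


def sleep_disturbance(series: RegularVolumeSeries, spec: SleepWindowSpec) -> float:
    """Pooled sample SD of volume values inside the sleep window.

    One SD over all qualifying samples (not an average of per-night SDs).
    Raises :class:`FeatureUndefinedError` with fewer than 2 qualifying
    samples.
    """
    vals = series.values[sleep_window_mask(series, spec)]
    if len(vals) < 2:
        raise FeatureUndefinedError(
            f"subject {series.subject_id}: fewer than 2 samples in sleep window "
            f"({spec.day_filter})"
        )
    return float(vals.std(ddof=1))


def speech_presence_ratio(log: RecordingLog) -> float:
    """Fraction of raw recordings in which speech was detected."""
    return float(log.speech.mean())


@dataclass(frozen=True)
class FeatureConfig:
    """Protocol constants for feature extraction."""

    lag_hours: float = 24.0
    sleep_start_hour: float = 0.0
    sleep_end_hour: float = 6.0
    period_min: int = 5
    clip_k: float = 3.0
    expected_count: int = 4032  # 14 days x 288 recordings/day
    sufficiency_threshold: float = 0.5


def extract_features(
    log: RecordingLog,
    preprocessed: RegularVolumeSeries | None = None,
    config: FeatureConfig = FeatureConfig(),
) -> FeatureRow:
    """Compute all four features for one subject.

    ``preprocessed`` may be supplied to skip the preprocessing chain.
    Undefined features (zero-variance segments, empty windows, constant
    series) become ``None`` cells; the row is retained either way, with
    ``included`` set by the sufficiency filter on the raw recording count.
    """
    included = sufficiency_filter(
        log, config.expected_count, config.sufficiency_threshold
    )
    ds = sd_all = sd_week = None
    try:
        if preprocessed is None:
            preprocessed = preprocess(log, config.period_min, config.clip_k)
        ds = _try(daily_similarity, preprocessed, config.lag_hours)
        all_spec = SleepWindowSpec(
            config.sleep_start_hour, config.sleep_end_hour, "all_nights"
        )
        week_spec = SleepWindowSpec(
            config.sleep_start_hour, config.sleep_end_hour, "weeknights"
        )
        sd_all = _try(sleep_disturbance, preprocessed, all_spec)
        sd_week = _try(sleep_disturbance, preprocessed, week_spec)
    except FeatureUndefinedError:
        pass  # preprocessing itself failed; all volume features missing
    return FeatureRow(
        subject_id=log.subject_id,
        daily_similarity=ds,
        sleep_disturbance_all=sd_all,
        sleep_disturbance_weeknights=sd_week,
        speech_presence_ratio=speech_presence_ratio(log),
        n_recordings=len(log),
        included=included,
    )


def _try(fn, *args):
    try:
        return fn(*args)
    except FeatureUndefinedError:
        return None
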