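"""Volume-series preprocessing: resampling, imputation, clipping, scaling.

The app records ambient volume roughly every 5 minutes but not at a precise
cadence, and slots are missed entirely when the OS suppresses background
work. The preprocessing chain turns the irregular log into the regular
series the behavioural features consume, in a fixed order:

    resample_and_impute -> clip_outliers -> minmax_scale

Resampling anchors the grid to wall-clock 5-minute boundaries so the
00:00–06:00 sleep window aligns exactly with grid points. An observation
within half a period of a grid point is *snapped* to it (cadence jitter
must not manufacture interpolated values); remaining gaps are filled by
linear interpolation between the bracketing observations, with no trend
extrapolation beyond the first/last observation. Outliers are clipped at
subject mean ± k·SD (sample SD, single pass), and the series is scaled
linearly onto [0, 1] — which also neutralises per-device gain, making the
pipeline unit-agnostic.
"""

from __future__ import annotations

import numpy as np

from .errors import FeatureUndefinedError, ParameterError
from .types import RecordingLog, RegularVolumeSeries


def resample_and_impute(log: RecordingLog, period_min: int = 5) -> RegularVolumeSeries:
    """Resample a raw log onto a regular wall-clock grid, imputing gaps.

    The grid starts at the last ``period_min`` boundary at or before the
    first observation and ends at the last boundary at or before the final
    observation. Each grid point takes the nearest observed value within
    ``period_min / 2`` minutes; otherwise the linear interpolant between
    the bracketing observations. Grid points before the first observation
    (at most one, when the first observation is off-boundary) hold the
    first observed value rather than extrapolating a trend.
    """
    if len(log) < 2:
        raise FeatureUndefinedError(
            f"subject {log.subject_id}: need >= 2 recordings to interpolate"
        )
    period_s = period_min * 60
    obs_t = log.timestamps.astype("int64")
    start = (obs_t[0] // period_s) * period_s
    # last boundary still snappable to the final observation (within half a
    # period); never beyond that, so no trailing extrapolation
    stop = ((obs_t[-1] + period_s // 2) // period_s) * period_s
    if stop <= start:
        raise FeatureUndefinedError(
            f"subject {log.subject_id}: observations span less than one grid step"
        )
    grid = np.arange(start, stop + 1, period_s)

    # nearest-observation snap within half a period
    idx = np.searchsorted(obs_t, grid)
    left = np.clip(idx - 1, 0, len(obs_t) - 1)
    right = np.clip(idx, 0, len(obs_t) - 1)
    dl = np.abs(grid - obs_t[left])
    dr = np.abs(obs_t[right] - grid)
    nearest = np.where(dl <= dr, left, right)  # tie -> earlier observation
    ndist = np.minimum(dl, dr)
    snapped = ndist <= period_s // 2

    values = np.interp(grid, obs_t, log.volumes)
    values[snapped] = log.volumes[nearest[snapped]]
    return RegularVolumeSeries(
        subject_id=log.subject_id,
        grid_start=grid[0].astype("datetime64[s]"),
        period_min=period_min,
        values=values,
        normalized=False,
    )


def clip_outliers(series: RegularVolumeSeries, k: float = 3.0) -> RegularVolumeSeries:
    """Clip values at the subject's mean ± ``k`` sample SDs, single pass.

    Bounds use this subject's own mean and SD (ddof=1), computed once from
    the pre-clip series; a constant series (SD 0) passes through unchanged.
    """
    if k <= 0:
        raise ParameterError(f"clip multiplier must be positive, got {k}")
    v = series.values
    m = v.mean()
    sd = v.std(ddof=1)
    clipped = np.clip(v, m - k * sd, m + k * sd)
    return RegularVolumeSeries(
        subject_id=series.subject_id,
        grid_start=series.grid_start,
        period_min=series.period_min,
        values=clipped,
        normalized=series.normalized,
    )


def minmax_scale(series: RegularVolumeSeries) -> RegularVolumeSeries:
    """Scale the series linearly onto [0, 1].

    Raises :class:`FeatureUndefinedError` for a constant (zero-range)
    series: such a subject cannot be featurized.
    """
    v = series.values
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise FeatureUndefinedError(
            f"subject {series.subject_id}: constant series, zero range"
        )
    return RegularVolumeSeries(
        subject_id=series.subject_id,
        grid_start=series.grid_start,
        period_min=series.period_min,
        values=(v - lo) / (hi - lo),
        normalized=True,
    )


def preprocess(
    log: RecordingLog, period_min: int = 5, clip_k: float = 3.0
) -> RegularVolumeSeries:
    """The full fixed-order chain: resample/impute, clip, scale."""
    return minmax_scale(clip_outliers(resample_and_impute(log, period_min), clip_k))


def sufficiency_filter(
    log: RecordingLog, expected_count: int = 4032, threshold: float = 0.5
) -> bool:
    """Inclusion rule: raw recording count >= threshold × expected count.

    The count is taken *before* resampling. The default expected count is
    the nominal protocol yield: 14 days × 288 recordings/day at a 5-minute
    period. The boundary is inclusive (exactly 50% passes).
    """
    if expected_count <= 0:
        raise ParameterError("expected_count must be positive")
    if not (0 < threshold <= 1):
        raise ParameterError(f"threshold must be in (0, 1], got {threshold}")
    return len(log) >= threshold * expected_count
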