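import numpy as np
import pytest

from volsense import RecordingLog, RegularVolumeSeries, SimulationParams

MONDAY = np.datetime64("2019-07-01T00:00:00", "s")  # a Monday, midnight


def make_series(values, start=MONDAY, period_min=5, normalized=False):
    return RegularVolumeSeries(
        subject_id="t",
        grid_start=np.datetime64(start, "s"),
        period_min=period_min,
        values=np.asarray(values, dtype=float),
        normalized=normalized,
    )


def make_log(minutes, volumes, speech=None, start=MONDAY, subject_id="t"):
    """Log with entries at `minutes` offsets from `start`."""
    minutes = np.asarray(minutes, dtype=float)
    ts = np.datetime64(start, "s") + (minutes * 60).astype("int64").astype(
        "timedelta64[s]"
    )
    if speech is None:
        speech = np.zeros(len(minutes), dtype=bool)
    return RecordingLog(
        subject_id=subject_id,
        timestamps=ts,
        volumes=np.asarray(volumes, dtype=float),
        speech=np.asarray(speech, dtype=bool),
    )


@pytest.fixture(scope="session")
def small_params():
    """A small, fast cohort: full 14-day protocol, 12 subjects."""
    return SimulationParams(n_subjects=12, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    from volsense import simulate_cohort

    return simulate_cohort(small_params)
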