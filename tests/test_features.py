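"""The four behavioural features: analytic limits, oracles, invariances."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import pearsonr

from volsense import (
    FeatureConfig,
    FeatureUndefinedError,
    SimulationParams,
    SleepWindowSpec,
    daily_similarity,
    extract_features,
    simulate_cohort,
    sleep_disturbance,
    speech_presence_ratio,
)
from volsense.features import sleep_window_mask
from volsense.pipeline import cohort_features

from .conftest import make_log, make_series

GRID_14D = np.arange(14 * 288) * 5 / 60.0  # hours at 5-min steps


class TestDailySimilarity:
    def test_exact_24h_periodic_signal_gives_one(self):
        v = np.sin(2 * np.pi * GRID_14D / 24.0)
        assert daily_similarity(make_series(v)) == pytest.approx(1.0, abs=1e-9)

    def test_12h_harmonic_also_gives_one_at_24h_lag(self):
        v = np.sin(2 * np.pi * GRID_14D / 12.0)
        assert daily_similarity(make_series(v)) == pytest.approx(1.0, abs=1e-9)

    def test_iid_noise_is_near_zero(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(size=4032)
        assert abs(daily_similarity(make_series(v))) < 0.05

    def test_matches_brute_force_segment_pearson(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(600, 1200))
            v = rng.normal(size=n).cumsum()  # smooth-ish random walk
            s = make_series(v)
            lag = 288
            oracle = pearsonr(v[:-lag], v[lag:]).statistic
            assert daily_similarity(s) == pytest.approx(oracle, abs=1e-12)

    def test_series_shorter_than_lag_errors(self):
        with pytest.raises(FeatureUndefinedError, match="too short"):
            daily_similarity(make_series(np.ones(289)))

    def test_zero_variance_segment_errors(self):
        v = np.concatenate([np.zeros(300), np.sin(np.arange(300))])
        with pytest.raises(FeatureUndefinedError, match="zero-variance"):
            daily_similarity(make_series(v), lag_hours=25.0)

    @given(
        a=st.floats(0.01, 50, allow_nan=False),
        b=st.floats(-100, 100, allow_nan=False),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_under_affine_rescaling(self, a, b, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=700)
        r1 = daily_similarity(make_series(v))
        r2 = daily_similarity(make_series(a * v + b))
        assert r1 == pytest.approx(r2, abs=1e-9)


class TestSleepDisturbance:
    def test_sample_sd_of_known_window_values(self):
        # first three grid points (00:00-00:10) hold 1,2,3; everything else
        # sits outside the 00:00-00:15 window
        v = np.array([1.0, 2.0, 3.0] + [9.0] * 285)
        spec = SleepWindowSpec(0.0, 0.25, "all_nights")
        assert sleep_disturbance(make_series(v), spec) == pytest.approx(1.0)

    def test_constant_night_gives_zero(self):
        hours = GRID_14D % 24
        v = np.where(hours < 6, 0.2, np.sin(GRID_14D))
        spec = SleepWindowSpec(0.0, 6.0, "all_nights")
        assert sleep_disturbance(make_series(v), spec) == 0.0

    def test_weekend_only_series_with_weeknights_filter_errors(self):
        saturday = np.datetime64("2019-07-06T00:00:00", "s")
        v = np.random.default_rng(1).uniform(size=2 * 288)  # Sat + Sun only
        s = make_series(v, start=saturday)
        with pytest.raises(FeatureUndefinedError, match="weeknights"):
            sleep_disturbance(s, SleepWindowSpec(0.0, 6.0, "weeknights"))

    def test_six_oclock_sample_is_excluded(self):
        s = make_series(np.arange(288, dtype=float))
        mask = sleep_window_mask(s, SleepWindowSpec(0.0, 6.0, "all_nights"))
        # half-open window: 00:00 included, 06:00 excluded -> 72 samples
        assert mask.sum() == 72
        assert not mask[72]  # the 06:00 grid point

    def test_monday_early_morning_counts_as_weeknight(self):
        monday = np.datetime64("2019-07-01T00:00:00", "s")
        s = make_series(np.arange(288, dtype=float), start=monday)
        mask = sleep_window_mask(s, SleepWindowSpec(0.0, 6.0, "weeknights"))
        assert mask.sum() == 72  # the night following Sunday is kept

    def test_matches_enumerated_window_oracle(self):
        rng = np.random.default_rng(7)
        v = rng.uniform(size=5 * 288)
        s = make_series(v)
        spec = SleepWindowSpec(0.0, 6.0, "weeknights")
        picked = [
            float(val)
            for t, val in zip(s.times(), v)
            if (t.astype("int64") % 86400) < 6 * 3600
            and ((t.astype("int64") // 86400 + 3) % 7) < 5
        ]
        oracle = np.std(picked, ddof=1)
        assert sleep_disturbance(s, spec) == pytest.approx(oracle, abs=1e-12)


class TestSpeechPresenceRatio:
    @pytest.mark.parametrize(
        "n_pos,n,expect", [(3, 20, 0.15), (0, 10, 0.0), (10, 10, 1.0)]
    )
    def test_counted_fixtures(self, n_pos, n, expect):
        speech = [True] * n_pos + [False] * (n - n_pos)
        log = make_log(np.arange(n) * 5.0, np.ones(n), speech)
        assert speech_presence_ratio(log) == pytest.approx(expect)

    def test_unaffected_by_volume_values(self):
        # the ratio uses the raw log only; volume content is irrelevant
        speech = [True, False, True, False]
        a = make_log([0, 5, 10, 15], [1, 2, 3, 4], speech)
        b = make_log([0, 5, 10, 15], [100, -5, 0.1, 7], speech)
        assert speech_presence_ratio(a) == speech_presence_ratio(b)


class TestExtractFeatures:
    def test_zero_dropout_subject_has_all_cells(self):
        params = SimulationParams(n_subjects=1, seed=3, dropout_base=0.0)
        logs, _, _ = simulate_cohort(params)
        row = extract_features(logs["S000"])
        assert row.n_recordings == 4032
        assert row.included
        for f in (
            row.daily_similarity,
            row.sleep_disturbance_all,
            row.sleep_disturbance_weeknights,
            row.speech_presence_ratio,
        ):
            assert f is not None

    def test_night_constant_subject_gets_zero_sleep_disturbance(self):
        hours = GRID_14D % 24
        v = np.where(hours < 6, 0.5, 0.5 + np.sin(GRID_14D) ** 2)
        series = make_series(v, normalized=True)
        log = make_log(GRID_14D * 60, v)
        row = extract_features(log, preprocessed=series)
        assert row.sleep_disturbance_all == 0.0
        assert row.daily_similarity is not None

    def test_undefined_features_become_missing_cells(self):
        # constant volume: preprocessing fails at minmax, volume features
        # missing, speech ratio still present, row retained
        log = make_log(np.arange(600) * 5.0, np.ones(600), [True] * 600)
        row = extract_features(log)
        assert row.daily_similarity is None
        assert row.sleep_disturbance_all is None
        assert row.speech_presence_ratio == 1.0


class TestMonotoneSensitivity:
    """Planted couplings move the features in the designed direction."""

    def _median_feature(self, feature, seeds=range(8), **kw):
        out = []
        for seed in seeds:
            params = SimulationParams(n_subjects=6, seed=seed, **kw)
            logs, _, truths = simulate_cohort(params)
            rows = cohort_features(logs)
            vals = [r.get(feature) for r in rows if r.get(feature) is not None]
            out.extend(vals)
        return np.median(out)

    def test_more_night_events_increase_sleep_disturbance(self):
        lo = self._median_feature(
            "sleep_disturbance_all", event_rate_base=0.2, event_rate_slope=0.0,
            event_rate_noise_sd=0.0,
        )
        hi = self._median_feature(
            "sleep_disturbance_all", event_rate_base=5.0, event_rate_slope=0.0,
            event_rate_noise_sd=0.0,
        )
        assert hi > lo

    def test_more_timing_jitter_decreases_daily_similarity(self):
        steady = self._median_feature(
            "daily_similarity", jitter_sd_base=0.05, jitter_sd_slope=0.0
        )
        erratic = self._median_feature(
            "daily_similarity", jitter_sd_base=2.5, jitter_sd_slope=0.0
        )
        assert erratic < steady
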