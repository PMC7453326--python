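"""Correlation/screening/group statistics against independent oracles."""

import numpy as np
import pytest
from scipy import stats

from volsense import (
    DEFAULT_SCREENING_RULES,
    FeatureRow,
    ParameterError,
    ScreeningRule,
    SubjectScales,
    VolsenseError,
    chi_square_2x2,
    correlation_table,
    pearson_with_p,
    screening_counts,
    t_test_two_groups,
)
from volsense.analysis import (
    age_scale_correlations,
    included_excluded_sex_table,
    sex_scale_tests,
)


def _scales_row(sid, phq8=10, age=30.0, sex="female", timepoint="exit", **kw):
    base = dict(lsas=50, gad7=5, sds=10)
    base.update(kw)
    return SubjectScales(sid, timepoint, base["lsas"], base["gad7"], phq8,
                         base["sds"], age, sex)


class TestPearsonWithP:
    def test_exact_positive_linearity(self):
        r, p, n = pearson_with_p([1, 2, 3], [2, 4, 6])
        assert r == 1.0 and p == 0.0 and n == 3

    def test_exact_negative_linearity(self):
        r, p, n = pearson_with_p([1, 2, 3], [6, 4, 2])
        assert r == -1.0 and p == 0.0

    def test_matches_scipy_on_random_pairs(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(3, 60))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            r, p, _ = pearson_with_p(x, y)
            ref = stats.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_small_or_constant_input_rejected(self):
        with pytest.raises(ParameterError):
            pearson_with_p([1, 2], [3, 4])
        with pytest.raises(ParameterError):
            pearson_with_p([1, 1, 1], [3, 4, 5])


class TestCorrelationTable:
    def _cohort(self, n=20, seed=3):
        rng = np.random.default_rng(seed)
        rows, scales = [], []
        for i in range(n):
            spr = float(rng.uniform(0.05, 0.4))
            rows.append(FeatureRow(f"s{i}", float(rng.uniform(0.5, 0.9)),
                                   float(rng.uniform(0.05, 0.3)),
                                   float(rng.uniform(0.05, 0.3)), spr, 4032, True))
            # make phq8 an exact affine function of the speech ratio; the
            # other scales vary freely
            scales.append(_scales_row(
                f"s{i}", phq8=int(round(4 + 40 * spr)),
                lsas=int(rng.integers(10, 100)), gad7=int(rng.integers(0, 21)),
                sds=int(rng.integers(0, 30)),
            ))
        return rows, scales

    def test_affine_scale_gives_near_unit_correlation(self):
        rows, scales = self._cohort()
        report = correlation_table(rows, scales)
        cell = report[("speech_presence_ratio", "phq8")]
        # integer rounding of the score is the only departure from r = 1
        assert cell.r > 0.99
        assert cell.n == 20

    def test_permutation_invariance(self):
        rows, scales = self._cohort()
        rng = np.random.default_rng(0)
        shuffled = list(rows)
        rng.shuffle(shuffled)
        a = correlation_table(rows, scales)
        b = correlation_table(shuffled, scales[::-1])
        for key in a:
            assert a[key] == b[key]

    def test_pairwise_deletion_of_missing_cells(self):
        rows, scales = self._cohort()
        rows[0] = FeatureRow("s0", None, rows[0].sleep_disturbance_all,
                             rows[0].sleep_disturbance_weeknights,
                             rows[0].speech_presence_ratio, 4032, True)
        report = correlation_table(rows, scales)
        assert report[("daily_similarity", "phq8")].n == 19
        assert report[("speech_presence_ratio", "phq8")].n == 20

    def test_excluded_rows_do_not_enter(self):
        rows, scales = self._cohort()
        rows[0] = FeatureRow("s0", 0.8, 0.1, 0.1, 0.2, 100, False)
        report = correlation_table(rows, scales)
        assert report[("speech_presence_ratio", "phq8")].n == 19

    def test_zero_join_is_an_error(self):
        rows = [FeatureRow("x", 0.8, 0.1, 0.1, 0.2, 100, False)]
        with pytest.raises(VolsenseError):
            correlation_table(rows, [_scales_row("x")])

    def test_benjamini_hochberg_only_raises_p(self):
        rows, scales = self._cohort()
        plain = correlation_table(rows, scales)
        adj = correlation_table(rows, scales, adjust="bh")
        for key in plain:
            assert adj[key].p >= plain[key].p - 1e-15
            assert adj[key].r == plain[key].r


class TestScreening:
    def test_cutoff_is_inclusive(self):
        scales = [_scales_row(f"s{i}", lsas=v) for i, v in enumerate([59, 60, 61])]
        res = screening_counts(scales, (ScreeningRule("lsas", 60),))
        assert res[0].positives == 2
        assert res[0].n == 3
        assert res[0].percent == pytest.approx(200 / 3)

    def test_all_below_cutoff(self):
        scales = [_scales_row(f"s{i}", phq8=3) for i in range(5)]
        res = screening_counts(scales, (ScreeningRule("phq8", 10),))
        assert res[0].positives == 0

    def test_default_rules_match_literature_cutoffs(self):
        cutoffs = {r.scale: r.cutoff for r in DEFAULT_SCREENING_RULES}
        assert cutoffs == {"lsas": 60, "gad7": 10, "phq8": 10}

    def test_empty_cohort_errors(self):
        with pytest.raises(VolsenseError):
            screening_counts([], DEFAULT_SCREENING_RULES)


class TestTTest:
    def test_identical_groups(self):
        res = t_test_two_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    def test_pooled_df_for_35_49_split(self):
        rng = np.random.default_rng(8)
        res = t_test_two_groups(rng.normal(size=35), rng.normal(size=49))
        assert res.df == 82

    def test_hand_arithmetic_oracle(self):
        # pooled variance 1, se = sqrt(2/3), t = -1/sqrt(2/3) = -sqrt(3/2)
        res = t_test_two_groups([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.statistic == pytest.approx(-np.sqrt(1.5), abs=1e-12)
        assert res.df == 4

    def test_tiny_group_rejected(self):
        with pytest.raises(ParameterError):
            t_test_two_groups([1.0], [2.0, 3.0])


class TestChiSquare:
    def test_proportional_table_is_independent(self):
        res = chi_square_2x2([[10, 20], [5, 10]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.df == 1

    def test_diagonal_table_oracle(self):
        # sum (O - E)^2 / E with all E = 5 -> 4 * 25/5 = 20
        res = chi_square_2x2([[10, 0], [0, 10]])
        assert res.statistic == pytest.approx(20.0)
        assert res.df == 1

    def test_zero_margin_rejected(self):
        with pytest.raises(ParameterError):
            chi_square_2x2([[0, 0], [5, 10]])


class TestDemographicHelpers:
    def test_age_correlation_recovers_planted_slope(self):
        rng = np.random.default_rng(4)
        scales = [
            _scales_row(f"s{i}", phq8=int(np.clip(round(24 - 0.4 * a), 0, 24)),
                        lsas=int(rng.integers(10, 100)), gad7=int(i % 9),
                        sds=int((2 * i) % 13), age=float(a))
            for i, a in enumerate(rng.integers(18, 60, size=40))
        ]
        r, p, n = age_scale_correlations(scales)["phq8"]
        assert r < -0.9 and n == 40

    def test_sex_tests_report_pooled_df(self):
        scales = [
            _scales_row(
                f"s{i}", phq8=(3 * i) % 11, lsas=20 + (7 * i) % 30,
                gad7=i % 8, sds=(2 * i) % 15, sex="female" if i < 6 else "male",
            )
            for i in range(15)
        ]
        assert sex_scale_tests(scales)["phq8"].df == 13

    def test_sex_by_inclusion_table(self):
        scales = [
            _scales_row(f"s{i}", sex="female" if i % 2 else "male")
            for i in range(6)
        ]
        rows = [
            FeatureRow(f"s{i}", 0.8, 0.1, 0.1, 0.2, 4032, included=i < 4)
            for i in range(6)
        ]
        table = included_excluded_sex_table(rows, scales)
        assert table.sum() == 6
        assert table[:, 0].sum() == 4  # included column
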