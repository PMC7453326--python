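"""Cohort statistics: screening, demographics, and feature-scale correlations.

Reproduces the study's analysis tables on the simulated cohort:
screening prevalence at the literature cutoffs (LSAS>=60, GAD-7>=10,
PHQ-8>=10), age correlations and sex t-tests per scale, the
included-vs-excluded sex chi-square, and the 4x4 feature x scale Pearson
grid (exit-timepoint scores, no multiple-testing correction).

Usage: python analysis/04_cohort_statistics.py
"""

from pathlib import Path

import pandas as pd

from volsense import DEFAULT_SCREENING_RULES, chi_square_2x2, correlation_table
from volsense.analysis import (
    age_scale_correlations,
    included_excluded_sex_table,
    screening_counts,
    sex_scale_tests,
)
from volsense.io_formats import (
    read_feature_table,
    read_scales,
    write_correlation_report,
)

COHORT = Path("results/cohort")


def main():
    rows = read_feature_table(COHORT / "features.csv")
    scales = read_scales(COHORT / "scales.csv")

    screens = screening_counts(scales, DEFAULT_SCREENING_RULES)
    pd.DataFrame(
        [{"scale": s.rule.scale, "cutoff": s.rule.cutoff,
          "positives": s.positives, "n": s.n, "percent": s.percent}
         for s in screens]
    ).to_csv(COHORT / "screening.csv", index=False)
    for s in screens:
        print(f"screening {s.rule.scale} >= {s.rule.cutoff}: "
              f"{s.positives}/{s.n} ({s.percent:.0f}%)")

    demo = []
    age_r = age_scale_correlations(scales)
    sex_t = sex_scale_tests(scales)
    for scale in age_r:
        r, p, n = age_r[scale]
        t = sex_t[scale]
        demo.append({"scale": scale, "age_r": r, "age_p": p,
                     "sex_t": t.statistic, "sex_df": t.df, "sex_p": t.p})
        print(f"{scale:5s} age r={r:+.2f} (p={p:.2f}); "
              f"sex t({t.df})={t.statistic:+.2f} (p={t.p:.2f})")
    pd.DataFrame(demo).to_csv(COHORT / "demographics.csv", index=False)

    table = included_excluded_sex_table(rows, scales)
    chi = chi_square_2x2(table)
    print(f"included-vs-excluded sex composition: "
          f"chi-square({chi.df}) = {chi.statistic:.2f}, p = {chi.p:.2f}")

    report = correlation_table(rows, scales, timepoint="exit")
    write_correlation_report(report, COHORT / "correlations.csv", "csv")
    write_correlation_report(report, COHORT / "correlations.json", "json")
    print("\nfeature x scale Pearson grid (r, two-sided p, n):")
    for feat, scale in report:
        c = report[(feat, scale)]
        print(f"  {feat:30s} {scale:5s} r={c.r:+.2f} p={c.p:.3f} n={c.n}")


if __name__ == "__main__":
    main()
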