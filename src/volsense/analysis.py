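"""Cohort-level statistics: feature–scale correlations and group tests.

The analysis is deliberately correlational: each behavioural feature is
tested against each self-report scale with a plain Pearson correlation
and a two-sided p-value from the t transformation, with **no** multiple-
testing correction by default (the analysis is exploratory; an optional
Benjamini–Hochberg flag exists for users who want it). Screening
prevalence uses inclusive cutoffs (score >= cutoff). Sex comparisons use
the pooled-variance Student t-test (df = n_a + n_b - 2) and
included-vs-excluded sex composition a 1-df Pearson chi-square without
continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ParameterError, VolsenseError
from .types import (
    FEATURES,
    SCALES,
    CorrelationCell,
    CorrelationReport,
    FeatureRow,
    GroupTestResult,
    ScreeningRule,
    SubjectScales,
)


def pearson_with_p(x, y) -> tuple[float, float, int]:
    """Product-moment correlation with a two-sided p-value.

    p comes from ``t = r * sqrt((n - 2) / (1 - r^2))`` on ``n - 2``
    degrees of freedom; at |r| = 1 the p-value is reported as the limit 0.
    Raises :class:`ParameterError` for n < 3 or a constant input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be paired 1-d arrays")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ParameterError("inputs must be finite")
    n = len(x)
    if n < 3:
        raise ParameterError(f"need n >= 3, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0 or sy == 0:
        raise ParameterError("constant input: correlation undefined")
    r = float(xc @ yc) / (sx * sy)
    r = min(1.0, max(-1.0, r))
    if 1.0 - abs(r) < 1e-12:  # exact collinearity up to float round-off
        return math.copysign(1.0, r), 0.0, n
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * float(stats.t.sf(abs(t), n - 2))
    return r, min(p, 1.0), n


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a reported correlation coefficient at sample size n.

    Uses the same t transformation as :func:`pearson_with_p`; handy for
    checking printed (r, n) pairs for internal consistency.
    """
    if not -1 <= r <= 1:
        raise ParameterError(f"r must be in [-1, 1], got {r}")
    if n < 3:
        raise ParameterError(f"need n >= 3, got {n}")
    if abs(r) == 1:
        return 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return min(1.0, 2 * float(stats.t.sf(abs(t), n - 2)))


def correlation_table(
    features: list[FeatureRow],
    scales: list[SubjectScales],
    timepoint: str = "exit",
    adjust: str | None = None,
) -> CorrelationReport:
    """Feature × scale Pearson grid over included subjects.

    Included feature rows are joined to the chosen-timepoint scale rows by
    subject id; a subject missing one feature cell is dropped pairwise
    from that cell only. ``adjust="bh"`` applies Benjamini–Hochberg to the
    p-values (off by default: no multiplicity correction).
    """
    by_subject = {s.subject_id: s for s in scales if s.timepoint == timepoint}
    # canonical subject order makes the result exactly permutation-invariant
    rows = sorted(
        (f for f in features if f.included and f.subject_id in by_subject),
        key=lambda f: f.subject_id,
    )
    if not rows:
        raise VolsenseError(
            "no included subjects with matching scale rows; nothing to analyse"
        )
    report = CorrelationReport()
    for feat in FEATURES:
        for scale in SCALES:
            pairs = [
                (f.get(feat), by_subject[f.subject_id].score(scale))
                for f in rows
                if f.get(feat) is not None
            ]
            try:
                r, p, n = pearson_with_p(
                    [a for a, _ in pairs], [b for _, b in pairs]
                )
                cell = CorrelationCell(r=r, p=p, n=n)
            except ParameterError:
                cell = CorrelationCell(r=None, p=None, n=len(pairs))
            report[(feat, scale)] = cell
    if adjust == "bh":
        _benjamini_hochberg(report)
    elif adjust is not None:
        raise ParameterError(f"unknown adjustment {adjust!r}")
    return report


def _benjamini_hochberg(report: CorrelationReport) -> None:
    keys = [k for k in report if report[k].p is not None]
    ps = np.array([report[k].p for k in keys])
    order = np.argsort(ps)
    m = len(ps)
    adj = np.empty(m)
    prev = 1.0
    for rank, i in list(enumerate(order, start=1))[::-1]:
        prev = min(prev, ps[i] * m / rank)
        adj[i] = prev
    for k, p in zip(keys, adj):
        cell = report[k]
        report[k] = CorrelationCell(r=cell.r, p=float(p), n=cell.n)


@dataclass(frozen=True)
class ScreeningResult:
    rule: ScreeningRule
    positives: int
    n: int

    @property
    def percent(self) -> float:
        return 100.0 * self.positives / self.n


def screening_counts(
    scales: list[SubjectScales],
    rules: tuple[ScreeningRule, ...],
    timepoint: str = "exit",
) -> list[ScreeningResult]:
    """Count positive screens per rule (inclusive >= cutoff)."""
    rows = [s for s in scales if s.timepoint == timepoint]
    if not rows:
        raise VolsenseError(f"no scale rows at timepoint {timepoint!r}")
    return [
        ScreeningResult(
            rule=rule,
            positives=sum(1 for s in rows if s.score(rule.scale) >= rule.cutoff),
            n=len(rows),
        )
        for rule in rules
    ]


def t_test_two_groups(values_a, values_b) -> GroupTestResult:
    """Pooled-variance (Student's) two-sample t-test, two-sided.

    df = n_a + n_b - 2. Requires at least 2 values per group.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ParameterError("zero pooled variance: t-test undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return GroupTestResult(statistic=float(t), df=len(a) + len(b) - 2, p=float(p))


def chi_square_2x2(table) -> GroupTestResult:
    """Pearson chi-square for a 2x2 table, 1 df, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ParameterError("table must be 2x2")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ParameterError("counts must be nonnegative integers")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ParameterError("zero margin: chi-square undefined")
    res = stats.chi2_contingency(obs, correction=False)
    return GroupTestResult(
        statistic=float(res.statistic), df=1, p=float(res.pvalue)
    )


def age_scale_correlations(
    scales: list[SubjectScales], timepoint: str = "exit"
) -> dict[str, tuple[float, float, int]]:
    """Pearson correlation of each scale score with age."""
    rows = [s for s in scales if s.timepoint == timepoint]
    if len(rows) < 3:
        raise VolsenseError("need at least 3 subjects for age correlations")
    age = [s.age for s in rows]
    return {
        scale: pearson_with_p([s.score(scale) for s in rows], age)
        for scale in SCALES
    }


def sex_scale_tests(
    scales: list[SubjectScales], timepoint: str = "exit"
) -> dict[str, GroupTestResult]:
    """Student t-test of each scale's mean between female and male subjects."""
    rows = [s for s in scales if s.timepoint == timepoint]
    female = [s for s in rows if s.sex == "female"]
    male = [s for s in rows if s.sex == "male"]
    return {
        scale: t_test_two_groups(
            [s.score(scale) for s in female], [s.score(scale) for s in male]
        )
        for scale in SCALES
    }


def included_excluded_sex_table(
    features: list[FeatureRow], scales: list[SubjectScales], timepoint: str = "exit"
) -> np.ndarray:
    """2x2 table of sex (rows: female, male) by inclusion (cols: in, out)."""
    sex = {s.subject_id: s.sex for s in scales if s.timepoint == timepoint}
    table = np.zeros((2, 2), dtype=int)
    for f in features:
        if f.subject_id not in sex:
            continue
        row = 0 if sex[f.subject_id] == "female" else 1
        col = 0 if f.included else 1
        table[row, col] += 1
    return table
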