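# Methods

## Data model and preprocessing

A recording log is one row per audio sample (nominally every 5 minutes
for 14 days, i.e. up to 4032 rows): a local wall-clock timestamp, a
volume value in arbitrary device units, and a binary speech-detected
flag. Timestamps are civil time without zone offsets; the sleep window
and day-of-week logic are deliberately defined on the clock the subject
lives by, and daylight-saving transitions are ignored (the
autocorrelation lag is a fixed 288 samples).

Preprocessing is a fixed chain:

1. **Resampling and imputation.** The grid is anchored to wall-clock
   5-minute boundaries (…:00, :05, …) so the 00:00–06:00 window aligns
   exactly with grid points; it runs from the boundary at or before the
   first observation to the last boundary within half a period of the
   final one. A grid point takes the nearest observation within half a
   period — cadence jitter in the recording app must not manufacture
   interpolated values — otherwise the linear interpolant between the
   bracketing observations. There is no trend extrapolation beyond the
   observed span: the at-most-one leading grid point before the first
   observation holds that observation's value. Interpolation gaps are
   unlimited by default (every missing sample is imputed); a cap could be
   added but the sufficiency filter already removes pathologically sparse
   subjects.
2. **Outlier clipping** at the subject's own mean ± 3 sample SDs
   (ddof = 1 to match the descriptive-statistics convention used
   elsewhere in the pipeline), bounds computed once from the pre-clip
   series (a single pass, not iterated). A constant series passes
   through (SD 0 ⇒ bounds collapse to the mean).
3. **Min–max scaling** onto [0, 1]. A zero-range (constant) series is an
   error: that subject cannot be featurized. Scaling neutralises the
   per-device multiplicative gain of uncontrolled phone microphones and
   makes the pipeline unit-agnostic (dB or linear input are both fine).

Inclusion uses the raw (pre-resampling) recording count with an
inclusive boundary: count ≥ 0.5 × 4032 admits the subject.

## Features

* **Daily similarity**: Pearson correlation of the preprocessed series
  with its 24-hour-lagged copy, each overlapping segment centred by its
  own mean. The segment-Pearson variant (rather than the global-mean
  autocovariance normalisation) was fixed because the two differ
  negligibly on 14-day series but a single definition is needed; the
  segment form is the plain "correlation of the signal and its shifted
  copy". It is invariant under affine rescaling, so normalisation cannot
  change it. Undefined when a segment has zero variance or the series is
  shorter than lag + 2.
* **Sleep disturbance**: one pooled sample SD over every value whose
  wall-clock time lies in the half-open window [00:00, 06:00) — not a
  mean of per-night SDs, since the definition is the SD of the windowed
  series. The *weeknights* variant keeps samples whose own calendar
  day-of-week is Monday–Friday; thus Monday 00:00–06:00 (the night
  following Sunday) is a weeknight and Saturday 00:00–06:00 is not. The
  alternative reading (nights following Mon–Fri evenings) was rejected
  to keep the rule a pure function of the sample's own timestamp.
* **Speech presence ratio**: speech-positive recordings over total
  recordings, computed on the *raw* log — the speech series is
  deliberately not preprocessed.

Undefined features become missing cells; the subject's row is retained
and the missing cell is dropped pairwise from the affected correlation
cells only (less destructive than listwise deletion, and exclusions stay
auditable via the run manifest).

## Statistics

`pearson_with_p` computes r from centred dot products and the two-sided
p from t = r·√((n−2)/(1−r²)) on n−2 df; |r| within 1e−12 of 1 is snapped
to ±1 with p = 0 (the limit; the unsnapped p would be below 1e−10
anyway). Cells need n ≥ 3 and non-constant inputs. No multiplicity
correction is applied by default — the analysis is exploratory — with an
optional Benjamini–Hochberg flag for users who want it. Sex comparisons
use the pooled-variance Student t (df = n₁ + n₂ − 2; the pooled form is
what yields df = 82 for a 35/49 split), and the included-vs-excluded sex
table a 1-df Pearson chi-square without continuity correction.
Screening cutoffs are inclusive: LSAS ≥ 60, GAD-7 ≥ 10, PHQ-8 ≥ 10.
Quartiles in descriptive summaries use linear interpolation between
order statistics. Exit-timepoint scores are analysed: a deployed system
would want to relate current behaviour to *current or upcoming* state,
not to severity reported two weeks before the data.

## The synthetic cohort generator

The generator exists so the pipeline can be validated by parameter
recovery; it emulates the statistical structure the analysis assumes,
not acoustics. Per subject, a latent severity s ~ Beta(1, 1) drives:

| mechanism | model | default |
|---|---|---|
| daily schedule | raised-cosine volume bump between wake and sleep | wake 08:00, sleep 23:00, amplitude 1 |
| timing jitter | per-day wake/sleep ~ N(nominal, j(s)²), j(s) = 0.25 + 0.4·s h | degrades daily similarity |
| night events | Poisson(e(s)) short positive excursions in 00:00–06:00, e(s) = 0.5 + 3·s + N(0, 1.5²) per night | inflates sleep disturbance |
| speech flags | Bernoulli, daytime q(s) = clip(0.35 − 0.25·s + N(0, 0.12²), 0, 0.75), night 0.01 | lowers speech ratio |
| device gain | volume × U(0.5, 2) | removed by scaling |
| dropout | i.i.d. per slot, 0.10; or per-subject Beta(1, 2) in the recruitment scenario | drives the sufficiency filter |
| texture | night floor 0.05, half-normal noise (day SD 0.15, night SD U(0.01, 0.06)), ±15 s timestamp jitter | |

Scale scores are round(clip(α + β·s + λ·u + ε)) with a shared standard
normal u loading on PHQ-8 (λ = 2.6) and SDS (λ = 4.15), chosen together
with the σ's so the population means/SDs sit near a typical online
convenience cohort (PHQ-8 ≈ 8.5 (5.6), SDS ≈ 10.8 (7.7), LSAS ≈ 54 (26),
GAD-7 ≈ 6.6 (4.6)) and corr(PHQ-8, SDS) ≈ 0.76. Age is mildly
negatively coupled to severity (Gaussian copula, loading 0.25); sex is
independent with P(female) = 35/84. Subject i uses
`default_rng([seed, i])`, so any subject's ground truth regenerates from
(params, seed, index) and whole cohorts are byte-reproducible.

The coupling slopes were fixed once by pilot simulation so that the
planted full-pipeline correlations against PHQ-8 land near |r| ≈
0.2–0.4 — the magnitude regime typical of passive-sensing studies —
with medians at the defaults of about −0.4 (daily similarity), +0.37
(sleep disturbance) and −0.4 (speech ratio). The speech–PHQ-8
correlation also has a closed-form clip-free target
(`expected_speech_phq8_corr`) used by the recovery tests.

What the generator does *not* emulate: any acoustic content, bursty or
diurnally-patterned missingness (dropout is i.i.d. by default),
weekday/weekend schedule differences (so the two sleep-disturbance
variants are nearly identical in simulation), scale-specific behavioural
signatures (one latent severity drives all four scales, so simulated
feature–scale correlations are similar across scales, unlike real
cohorts where depression associations dominate), enrollment dynamics, or
withdrawals. Passing tests therefore demonstrate that the pipeline
recovers planted structure of realistic magnitude and is calibrated
under the null — not that real data would show these effect sizes.

## Validation design

* **Oracle equivalence**: daily similarity against an independent
  segment-Pearson computation, sleep disturbance against the SD of
  explicitly enumerated window values, preprocessing against closed
  forms (tolerance 1e−12).
* **Analytic limits**: 24-h- and 12-h-periodic signals give daily
  similarity 1; night-constant series give sleep disturbance 0.
* **Type-I calibration**: on cohorts with all couplings zeroed, each of
  the 16 feature × scale cells rejects at α = 0.05 at close to the
  nominal rate (a 600-seed diagnostic run gave per-cell rates
  0.048–0.063).
* **Planted recovery**: at the default couplings the designed sign
  pattern is reproduced in ≥ 95% of seeds and the median recovered
  speech–PHQ-8 r sits within ±0.15 of its analytic target.

Cohort-level studies use 84-subject, 14-day cohorts (the full protocol
size) with 100–200 seeds; these sizes give binomial/Monte-Carlo error
well below the asserted tolerances while keeping a full validation run
around a minute.

## Known limitations

* The half-open [00:00, 06:00) window and the calendar-day weeknight
  rule are fixed conventions; "between 12 AM and 6 AM" and "weeknights"
  admit other readings, and a study comparing against externally
  computed features should confirm the convention matches.
* Whether 3-SD clipping should use sample or population SD is a
  convention; sample SD is used. The two differ by O(1/n) on 4000-point
  series.
* The expected recording count in the sufficiency filter is the nominal
  protocol yield (4032), not each subject's actual enrollment span.
* Pearson correlations on a bounded, sometimes skewed feature such as
  the speech ratio are slightly anticonservative at n = 84 (null
  rejection ~0.05–0.06 rather than exactly 0.05); rank correlations
  would be the robust alternative but are not what this analysis
  specifies.
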