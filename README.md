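# volsense

Passive ambient-audio phenotyping for mental-health research: a tested
pipeline from raw smartphone environment-volume logs to behavioural
features and cohort-level correlation statistics against self-report
symptom scales.

## The problem

A smartphone can sample the *volume* of its owner's acoustic environment
every few minutes — a privacy-light signal that still reflects daily
activity rhythm, night-time noise, and exposure to speech. In
passive-sensing (passive EMA) studies, such logs are collected for two
weeks alongside standard self-report scales — the Liebowitz Social
Anxiety Scale (LSAS, 0–144), the GAD-7 (0–21), the PHQ-8 (0–24) and the
Sheehan Disability Scale (SDS, 0–30) — and the question is whether simple
features of the audio stream correlate with symptom severity.

`volsense` implements that analysis end to end:

* **Preprocessing.** Each subject's irregular volume log is resampled to
  a 5-minute wall-clock grid (nearest-observation snapping within half a
  period, linear interpolation of gaps), clipped at the subject's mean
  ± 3 sample SDs, and min–max scaled onto [0, 1] — which also removes
  per-device gain. Subjects with fewer than 50% of the 4032 recordings a
  14-day, 5-minute protocol would yield are excluded.
* **Features.** Four per subject:
  * *daily similarity* = ρ(v<sub>t</sub>, v<sub>t+24h</sub>), the Pearson
    autocorrelation of the preprocessed series at a 24-hour lag
    (288 samples) — day-to-day regularity of activity;
  * *sleep disturbance* (all nights / weeknights) = the pooled sample SD
    of values with wall-clock time in [00:00, 06:00) — night-time
    environmental noise as a sleep-quality proxy;
  * *speech presence ratio* = the fraction of raw recordings in which
    speech was detected — a context-unaware social-interaction proxy.
* **Statistics.** Pearson r with two-sided p (t transformation, n−2 df)
  for each feature × scale cell at the exit timepoint, no multiplicity
  correction; screening prevalence at LSAS ≥ 60, GAD-7 ≥ 10, PHQ-8 ≥ 10;
  age correlations; pooled-variance sex t-tests; and a 1-df chi-square
  for included-vs-excluded sex composition.
* **Synthetic cohorts.** Raw study data of this kind are not shareable,
  so a generator produces cohorts in which a latent severity s ∈ [0, 1]
  drives wake/sleep timing jitter, night noise events, daytime speech
  probability, and the scale scores (with a shared factor giving
  corr(PHQ-8, SDS) ≈ 0.76). Every stage of the pipeline is validated by
  parameter recovery and type-I calibration on these cohorts.

## Worked example

The numbered drivers under `analysis/` run the full study on a simulated
recruitment-style cohort (112 subjects, heterogeneous dropout):

```sh
python analysis/01_simulate_cohort.py --seed 0
python analysis/02_preprocess_inclusion.py
python analysis/03_extract_features.py
python analysis/04_cohort_statistics.py
```

which prints, among other things:

```
79 of 112 subjects meet the 50% sufficiency criterion (median yield 76% of protocol)
                     feature  n  mean    sd   min    q1    q2    q3   max
            daily_similarity 79 0.925 0.027 0.875 0.903 0.927 0.951 0.968
       sleep_disturbance_all 79 0.088 0.044 0.004 0.060 0.093 0.120 0.157
...
  daily_similarity               phq8  r=-0.51 p=0.000 n=79
  sleep_disturbance_all          phq8  r=+0.37 p=0.001 n=79
  speech_presence_ratio          phq8  r=-0.46 p=0.000 n=79
```

Read: about a quarter of the simulated cohort fails the data-sufficiency
filter; among included subjects, more regular days (higher daily
similarity) and more speech exposure go with *lower* depression scores,
and noisier nights with *higher* ones — the sign pattern the generator
plants and the analysis recovers. `analysis/05_calibration_studies.py`
repeats the pipeline over hundreds of seeds to verify type-I calibration
on null cohorts and sign/effect recovery on planted ones.

The same stages are available as a CLI (`volsense simulate | preprocess |
extract-features | analyze | summarize | run-full`), e.g.:

```sh
volsense run-full --seed 1 --out-dir out/
```

which writes the features CSV, the correlation report (CSV + JSON) and a
run manifest with per-stage subject accounting.

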