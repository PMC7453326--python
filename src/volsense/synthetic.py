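"""Synthetic cohort generator for ambient-audio phenotyping studies.

Real study data of this kind (passively recorded environment-volume logs
with linked symptom scales) are essentially never shareable, so every
downstream stage is exercised against simulated cohorts with the same
statistical structure the analysis assumes:

* a latent symptom **severity** ``s`` in [0, 1] per subject drives both
  the behaviour in the audio stream and the self-report scores;
* each day has a loud waking period (a raised-cosine volume bump between
  wake and sleep times, plus positive activity spikes) and a quiet night
  floor; day-to-day **timing jitter** of wake/sleep grows with severity,
  degrading the 24-h autocorrelation;
* nights contain Poisson-distributed **noise events** whose rate grows
  with severity, inflating the sleep-window SD;
* each recording carries a Bernoulli **speech flag** whose daytime
  probability falls with severity;
* a per-subject multiplicative **gain** models uncontrolled microphone
  hardware and AGC (neutralised downstream by min–max scaling), and slots
  are dropped i.i.d. to model missed recordings;
* scale scores are ``round(clip(alpha + beta*s + loading*u + noise))``
  with a shared Gaussian factor ``u`` between PHQ-8 and SDS so that
  depression and impairment scores are strongly dependent (population
  r ≈ 0.76), as observed in this kind of cohort.

Volume is generated on a linear positive scale (not dB); absolute units
are arbitrary by design since the pipeline normalises per subject.

Everything is reproducible: subject ``i`` of a cohort uses
``np.random.default_rng([seed, i])``, so ground truth can be regenerated
from (params, seed, subject index) alone.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .errors import ParameterError
from .types import SCALE_RANGES, RecordingLog, SubjectScales


@dataclass(frozen=True)
class ScaleMap:
    """Linear-in-severity score model for one scale.

    score = round(clip(alpha + beta*s + shared_loading*u + N(0, sigma)))
    with u the subject/timepoint-level shared Gaussian factor.
    """

    alpha: float
    beta: float
    sigma: float
    shared_loading: float = 0.0


#: Default score maps, chosen so that with s ~ Uniform(0, 1) the
#: population mean/SD of each scale sit near values typical of an online
#: convenience cohort (LSAS ~ 54 (26), GAD-7 ~ 6.6 (4.6), PHQ-8 ~ 8.5
#: (5.6), SDS ~ 10.8 (7.7)) and corr(PHQ-8, SDS) ~ 0.76 via the shared
#: factor.
DEFAULT_SCALE_MAPS: dict[str, ScaleMap] = {
    "lsas": ScaleMap(alpha=20.0, beta=67.5, sigma=16.9),
    "gad7": ScaleMap(alpha=1.0, beta=11.2, sigma=3.3),
    "phq8": ScaleMap(alpha=1.0, beta=15.0, sigma=2.42, shared_loading=2.6),
    "sds": ScaleMap(alpha=2.0, beta=17.6, sigma=4.04, shared_loading=4.15),
}


@dataclass(frozen=True)
class SimulationParams:
    """All knobs of the cohort generator, with study-protocol defaults.

    Couplings to the latent severity s:

    * wake/sleep jitter SD (hours) = ``jitter_sd_base + jitter_sd_slope*s``
    * night event rate (events/night) = ``event_rate_base +
      event_rate_slope*s`` plus subject-level Gaussian noise
    * daytime speech probability = ``speech_day_base -
      speech_day_slope*s`` plus subject-level Gaussian noise, clipped to
      [0, speech_day_max]
    * dropout probability = ``dropout_base + dropout_slope*s`` unless
      ``dropout_beta`` is set, in which case each subject draws dropout
      from Beta(a, b) (used to emulate heterogeneous data yield).
    """

    n_subjects: int = 84
    study_days: int = 14
    sampling_period_min: int = 5
    seed: int = 0
    start: str = "2019-07-01T00:00:00"  # a Monday, at midnight

    # latent severity s ~ Beta(a, b); (1, 1) = uniform
    severity_a: float = 1.0
    severity_b: float = 1.0

    # daily schedule (hours of day)
    wake_hour: float = 8.0
    sleep_hour: float = 23.0
    jitter_sd_base: float = 0.25
    jitter_sd_slope: float = 0.4

    # night noise events
    event_rate_base: float = 0.5
    event_rate_slope: float = 3.0
    event_rate_noise_sd: float = 1.5
    event_height: tuple[float, float] = (0.3, 0.9)
    event_max_len_slots: int = 3

    # speech presence
    speech_day_base: float = 0.35
    speech_day_slope: float = 0.25
    speech_subject_sd: float = 0.12
    speech_day_max: float = 0.75
    speech_night: float = 0.01

    # volume texture (linear, arbitrary units before gain)
    diurnal_amplitude: float = 1.0
    night_floor: float = 0.05
    day_noise_sd: float = 0.15
    night_noise_sd_range: tuple[float, float] = (0.01, 0.06)

    # hardware / missingness
    gain_range: tuple[float, float] = (0.5, 2.0)
    dropout_base: float = 0.10
    dropout_slope: float = 0.0
    dropout_beta: tuple[float, float] | None = None
    timestamp_jitter_s: float = 15.0

    # demographics
    age_mean: float = 30.0
    age_sd: float = 8.6
    age_severity_loading: float = 0.25  # younger subjects skew more severe
    female_fraction: float = 35 / 84

    scale_maps: dict[str, ScaleMap] = field(
        default_factory=lambda: dict(DEFAULT_SCALE_MAPS)
    )

    def __post_init__(self):
        if self.n_subjects <= 0:
            raise ParameterError("n_subjects must be positive")
        if self.study_days <= 0 or self.sampling_period_min <= 0:
            raise ParameterError("study_days and sampling_period_min must be positive")
        if (1440 % self.sampling_period_min) != 0:
            raise ParameterError("sampling_period_min must divide 1440")
        if not (0 <= self.wake_hour < self.sleep_hour <= 24):
            raise ParameterError("need 0 <= wake_hour < sleep_hour <= 24")
        for name in ("jitter_sd_slope", "event_rate_slope", "speech_day_slope"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for p in (self.speech_day_base, self.speech_night, self.female_fraction):
            if not 0 <= p <= 1:
                raise ParameterError(f"probability {p} outside [0, 1]")
        if self.speech_day_base - self.speech_day_slope < -0.5:
            raise ParameterError("speech_day coupling drives probability far below 0")
        if self.dropout_beta is None:
            for s in (0.0, 1.0):
                d = self.dropout_base + self.dropout_slope * s
                if not 0 <= d < 1:
                    raise ParameterError(
                        f"dropout probability {d} outside [0, 1) at severity {s}"
                    )
        if self.scale_maps["phq8"].beta <= 0:
            raise ParameterError("phq8 beta must be positive")
        if self.timestamp_jitter_s * 2 >= self.sampling_period_min * 60:
            raise ParameterError("timestamp jitter must be below half a period")
        start = np.datetime64(self.start, "s").astype("int64")
        if start % 86400 != 0:
            raise ParameterError("start must be at local midnight")

    @property
    def slots_per_day(self) -> int:
        return 1440 // self.sampling_period_min

    @property
    def n_slots(self) -> int:
        return self.study_days * self.slots_per_day

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scale_maps"] = {k: asdict(v) for k, v in self.scale_maps.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        d = dict(d)
        if "scale_maps" in d:
            d["scale_maps"] = {
                k: ScaleMap(**v) if isinstance(v, dict) else v
                for k, v in d["scale_maps"].items()
            }
        for key in ("event_height", "night_noise_sd_range", "gain_range",
                    "dropout_beta"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def with_couplings_zeroed(self) -> "SimulationParams":
        """Null-cohort variant: severity decoupled from every behaviour."""
        return replace(
            self,
            jitter_sd_slope=0.0,
            event_rate_slope=0.0,
            speech_day_slope=0.0,
            dropout_slope=0.0,
        )


@dataclass(frozen=True)
class SubjectGroundTruth:
    """Latent quantities behind one simulated subject."""

    subject_id: str
    severity: float
    gain: float
    dropout: float
    event_rate: float
    speech_day_prob: float
    jitter_sd: float
    wake_hours: tuple[float, ...]
    sleep_hours: tuple[float, ...]
    event_counts: tuple[int, ...]


def diurnal_bump(
    t: np.ndarray | float, wake: float, sleep: float, amplitude: float
) -> np.ndarray | float:
    """Raised-cosine daytime volume bump.

    Zero outside [wake, sleep] (hours of day), smooth inside, maximum
    ``amplitude`` at the interval midpoint. Its integral over the day is
    ``amplitude * (sleep - wake) / 2``.
    """
    if amplitude < 0:
        raise ParameterError("amplitude must be >= 0")
    if not wake < sleep:
        raise ParameterError("need wake < sleep")
    t = np.asarray(t, dtype=float)
    phase = (t - wake) / (sleep - wake)
    inside = (phase >= 0) & (phase <= 1)
    out = np.where(inside, 0.5 * amplitude * (1 - np.cos(2 * np.pi * phase)), 0.0)
    return out if out.ndim else float(out)


def simulate_scales(
    s: float,
    params: SimulationParams,
    rng: np.random.Generator,
    subject_id: str = "s",
    timepoint: str = "exit",
    age: float = 30.0,
    sex: str = "female",
) -> SubjectScales:
    """Draw one subject's scale scores at one timepoint from severity ``s``.

    A single shared standard-normal factor ``u`` is drawn per call and
    enters every scale through its ``shared_loading`` (nonzero for PHQ-8
    and SDS only, by default). Scores are rounded and clipped into each
    scale's closed range, so output is always valid.
    """
    if not 0 <= s <= 1:
        raise ParameterError(f"severity {s} outside [0, 1]")
    u = rng.standard_normal()
    scores = {}
    for scale, m in params.scale_maps.items():
        lo, hi = SCALE_RANGES[scale]
        raw = m.alpha + m.beta * s + m.shared_loading * u + rng.normal(0.0, m.sigma)
        scores[scale] = int(np.clip(round(raw), lo, hi))
    return SubjectScales(
        subject_id=subject_id, timepoint=timepoint, age=age, sex=sex, **scores
    )


def _simulate_subject(
    i: int, params: SimulationParams
) -> tuple[RecordingLog, list[SubjectScales], SubjectGroundTruth]:
    rng = np.random.default_rng([params.seed, i])
    sid = f"S{i:03d}"
    p = params

    s = float(rng.beta(p.severity_a, p.severity_b))
    # mild negative age-severity dependence via a Gaussian copula on s's
    # normal score (exact for uniform severity)
    z_s = _norm_ppf(min(max(s, 1e-9), 1 - 1e-9))
    lam = p.age_severity_loading
    age_z = -lam * z_s + math.sqrt(max(0.0, 1 - lam**2)) * rng.standard_normal()
    age = float(np.clip(round(p.age_mean + p.age_sd * age_z), 18, 75))
    sex = "female" if rng.random() < p.female_fraction else "male"

    gain = float(rng.uniform(*p.gain_range))
    if p.dropout_beta is not None:
        dropout = float(rng.beta(*p.dropout_beta))
    else:
        dropout = p.dropout_base + p.dropout_slope * s
    jitter_sd = p.jitter_sd_base + p.jitter_sd_slope * s
    event_rate = max(
        0.0, p.event_rate_base + p.event_rate_slope * s
        + rng.normal(0.0, p.event_rate_noise_sd)
    )
    q_day = float(np.clip(
        p.speech_day_base - p.speech_day_slope * s
        + rng.normal(0.0, p.speech_subject_sd),
        0.0, p.speech_day_max,
    ))
    sigma_night = float(rng.uniform(*p.night_noise_sd_range))

    wake = np.clip(
        p.wake_hour + rng.normal(0.0, jitter_sd, p.study_days),
        p.wake_hour - 4.0, p.wake_hour + 4.0,
    )
    sleep = np.clip(
        p.sleep_hour + rng.normal(0.0, jitter_sd, p.study_days),
        p.sleep_hour - 4.0, min(p.sleep_hour + 4.0, 23.999),
    )
    sleep = np.maximum(sleep, wake + 4.0)  # degenerate days cannot invert

    n = p.n_slots
    spd = p.slots_per_day
    period_s = p.sampling_period_min * 60
    start_s = np.datetime64(p.start, "s").astype("int64")
    slot_s = start_s + np.arange(n, dtype="int64") * period_s
    hour = (slot_s % 86400) / 3600.0
    day_idx = (slot_s - start_s) // 86400

    w = wake[day_idx]
    sl = sleep[day_idx]
    phase = (hour - w) / (sl - w)
    in_day = (phase >= 0) & (phase <= 1)
    bump = np.where(
        in_day, 0.5 * p.diurnal_amplitude * (1 - np.cos(2 * np.pi * phase)), 0.0
    )
    noise_sd = np.where(in_day, p.day_noise_sd, sigma_night)
    inner = p.night_floor + bump + np.abs(rng.standard_normal(n)) * noise_sd

    # night noise events: Poisson per night, short positive excursions in
    # the 00:00-06:00 window
    h_lo, h_hi = p.event_height
    event_counts = rng.poisson(event_rate, p.study_days)
    for d in range(p.study_days):
        for _ in range(event_counts[d]):
            length = int(rng.integers(1, p.event_max_len_slots + 1))
            start_hour = rng.uniform(0.0, 6.0 - length * p.sampling_period_min / 60)
            i0 = d * spd + int(start_hour * 3600 // period_s)
            inner[i0 : i0 + length] += rng.uniform(h_lo, h_hi)

    volume = gain * inner
    q_slot = np.where(in_day, q_day, p.speech_night)
    speech = rng.random(n) < q_slot

    ts = slot_s.astype(float)
    if p.timestamp_jitter_s > 0:
        ts = ts + rng.uniform(-p.timestamp_jitter_s, p.timestamp_jitter_s, n)
    ts = np.round(ts).astype("int64")

    keep = rng.random(n) >= dropout
    if keep.sum() < 2:  # pathological dropout; keep the log constructible
        keep[:2] = True
    log = RecordingLog(
        subject_id=sid,
        timestamps=ts[keep].astype("datetime64[s]"),
        volumes=volume[keep],
        speech=speech[keep],
    )
    scales = [
        simulate_scales(s, p, rng, sid, tp, age, sex) for tp in ("intake", "exit")
    ]
    truth = SubjectGroundTruth(
        subject_id=sid,
        severity=s,
        gain=gain,
        dropout=float(dropout),
        event_rate=float(event_rate),
        speech_day_prob=q_day,
        jitter_sd=float(jitter_sd),
        wake_hours=tuple(float(x) for x in wake),
        sleep_hours=tuple(float(x) for x in sleep),
        event_counts=tuple(int(c) for c in event_counts),
    )
    return log, scales, truth


def simulate_cohort(
    params: SimulationParams,
) -> tuple[dict[str, RecordingLog], list[SubjectScales], list[SubjectGroundTruth]]:
    """Generate a full cohort: recording logs, scale rows (intake + exit),
    and the per-subject ground truth behind them.

    Identical (params, seed) always produces identical output.
    """
    logs: dict[str, RecordingLog] = {}
    scales: list[SubjectScales] = []
    truths: list[SubjectGroundTruth] = []
    for i in range(params.n_subjects):
        log, sc, truth = _simulate_subject(i, params)
        logs[log.subject_id] = log
        scales.extend(sc)
        truths.append(truth)
    return logs, scales, truths


def expected_speech_phq8_corr(params: SimulationParams) -> float:
    """Analytic (clip-free, large-sample) target for the planted
    correlation between the speech presence ratio and the PHQ-8 score.

    Both quantities are approximately linear in severity s: the speech
    ratio is ``const - f_day * speech_day_slope * s`` plus subject-level
    noise (f_day = waking fraction of the day), and PHQ-8 is
    ``alpha + beta*s`` plus its noise terms. Binomial sampling noise in
    the ratio (thousands of recordings per subject) is negligible and is
    ignored.
    """
    p = params
    a, b = p.severity_a, p.severity_b
    var_s = a * b / ((a + b) ** 2 * (a + b + 1))
    f_day = (p.sleep_hour - p.wake_hour) / 24.0
    m = p.scale_maps["phq8"]
    cov = -f_day * p.speech_day_slope * m.beta * var_s
    sd_ratio = math.sqrt(
        (f_day * p.speech_day_slope) ** 2 * var_s
        + (f_day * p.speech_subject_sd) ** 2
    )
    sd_phq8 = math.sqrt(m.beta**2 * var_s + m.sigma**2 + m.shared_loading**2)
    return cov / (sd_ratio * sd_phq8)


def _norm_ppf(q: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(q))


def ground_truth_frame(truths: list[SubjectGroundTruth]):
    """Per-subject ground-truth summary as a DataFrame (for the CSV)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "subject_id": t.subject_id,
                "severity": t.severity,
                "gain": t.gain,
                "dropout": t.dropout,
                "event_rate": t.event_rate,
                "speech_day_prob": t.speech_day_prob,
                "jitter_sd": t.jitter_sd,
                "mean_wake_hour": float(np.mean(t.wake_hours)),
                "mean_sleep_hour": float(np.mean(t.sleep_hours)),
                "total_night_events": int(sum(t.event_counts)),
            }
            for t in truths
        ]
    )
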