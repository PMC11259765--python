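"""Synthetic minute-level nights and day-level menstrual cycles.

Two forward models make every stage of the pipeline testable without any
recorded data:

* **Night model** — a constant true core temperature drives skin
  temperature through the steady-state heat-flux relation
  ``Ts = (K·Ta + CBT)/(1+K)`` against a drifting, smoothly varying ambient
  path, plus Gaussian sensor noise, a warm-up transient over roughly the
  first hour (the sensor equilibrating after application), and optional
  sensor-displacement artifacts (brief sharp skin-temperature drops).

* **Cycle model** — daily representative temperature is a follicular
  baseline plus, for ovulatory cycles, a smooth luteal rise of magnitude
  ``luteal_shift`` ramping over ``shift_ramp_days`` around the ovulation
  day, plus daily noise; days are masked missing at random. A positive
  urine LH test is placed one day before ovulation (the LH surge precedes
  ovulation by about a day); preceding test days are negative, and
  anovulatory cycles test negative throughout.

Defaults follow the reference population: follicular mean 36.48 °C
(between-subject SD 0.22 °C) and a between-phase change of 0.41 °C
(SD 0.20 °C).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date as _date
from datetime import datetime, timedelta
import numpy as np
import pandas as pd

from .cycles import SOURCE_ESTIMATED_CBT, DailySeries, LHResult
from .heatflux import NightRecording, NightSummary, QualityFlag, TemperatureSample, skin_from_cbt

__all__ = [
    "CycleSimParams",
    "NightSimParams",
    "CycleTruth",
    "Cohort",
    "generate_cycle",
    "generate_night",
    "generate_cohort",
]

FOLLICULAR_MEAN = 36.48
FOLLICULAR_BETWEEN_SUBJECT_SD = 0.22
LUTEAL_SHIFT_MEAN = 0.41
LUTEAL_SHIFT_SD = 0.20
LUTEAL_SHIFT_FLOOR = 0.05

# first LH test day: testing starts after menstruation ends (~5 days)
LH_TEST_START_DAY = 6


@dataclass
class CycleSimParams:
    """Day-level cycle simulation settings.

    ``luteal_shift=None`` draws the shift from N(0.41, 0.20) truncated at
    0.05 °C; ``ovulation_day=None`` places ovulation 14 days before the
    next menses with an integer jitter of ±2 days (a 12–16 day luteal
    phase).
    """

    length_days: int = 28
    ovulatory: bool = True
    follicular_mean: float = FOLLICULAR_MEAN
    luteal_shift: float | None = None
    shift_ramp_days: int = 2
    ovulation_day: int | None = None
    daily_noise_sd: float = 0.10
    missing_prob: float = 0.10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.daily_noise_sd < 0 or not 0 <= self.missing_prob <= 1:
            raise ValueError("invalid noise or missingness settings")
        if self.ovulation_day is not None and not (
            10 <= self.ovulation_day <= self.length_days - 10
        ):
            raise ValueError("ovulation_day must lie in [10, length−10]")


@dataclass
class NightSimParams:
    """Minute-level night simulation settings."""

    true_cbt: float = 36.9
    k_true: float = 0.2
    ambient_mean: float = 24.0
    ambient_drift: float = -0.3  # °C per hour
    ambient_noise_sd: float = 0.3  # sd of the smooth ambient wander
    sensor_noise_sd: float = 0.05
    artifact_prob: float = 0.0
    duration_min: int = 420
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.duration_min < 1:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class CycleTruth:
    cycle_id: str
    ovulatory: bool
    ovulation_day: int | None
    luteal_shift: float | None


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _ramp(day: np.ndarray, ovulation_day: int, ramp_days: int) -> np.ndarray:
    """Smoothstep rise from 0 at the ovulation day to 1 after ``ramp_days``."""
    if ramp_days <= 0:
        return (day > ovulation_day).astype(float)
    f = np.clip((day - ovulation_day) / ramp_days, 0.0, 1.0)
    return 3 * f**2 - 2 * f**3


def generate_cycle(
    p: CycleSimParams,
    cycle_id: str = "sim",
    subject_id: str = "s01",
    rng: np.random.Generator | None = None,
) -> tuple[DailySeries, list[LHResult], CycleTruth]:
    """Simulate one cycle's daily series, LH tests and ground truth."""
    rng = _rng(rng if rng is not None else p.seed)
    days = np.arange(1, p.length_days + 1)

    ovulation_day = None
    shift = None
    profile = np.full(p.length_days, p.follicular_mean, dtype=float)
    if p.ovulatory:
        ovulation_day = (
            p.ovulation_day
            if p.ovulation_day is not None
            else int(p.length_days - 14 + rng.integers(-2, 3))
        )
        if p.luteal_shift is not None:
            shift = float(p.luteal_shift)
        else:
            shift = float(
                max(LUTEAL_SHIFT_FLOOR, rng.normal(LUTEAL_SHIFT_MEAN, LUTEAL_SHIFT_SD))
            )
        profile = profile + shift * _ramp(days, ovulation_day, p.shift_ramp_days)
    if p.daily_noise_sd > 0:
        profile = profile + rng.normal(0.0, p.daily_noise_sd, size=p.length_days)
    observed = rng.random(p.length_days) >= p.missing_prob
    values = {int(d): float(v) for d, v, m in zip(days, profile, observed) if m}

    lh: list[LHResult] = []
    last_test = (ovulation_day - 1) if p.ovulatory else p.length_days
    for d in range(LH_TEST_START_DAY, last_test + 1):
        positive = p.ovulatory and d == ovulation_day - 1
        lh.append(LHResult(cycle_day=d, result="positive" if positive else "negative"))

    series = DailySeries(
        cycle_id=cycle_id,
        subject_id=subject_id,
        length_days=p.length_days,
        values=values,
        source=SOURCE_ESTIMATED_CBT,
    )
    truth = CycleTruth(cycle_id, p.ovulatory, ovulation_day, shift)
    return series, lh, truth


def _smooth_noise(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Slowly wandering zero-mean noise: white noise through a 21-min window."""
    if sd <= 0:
        return np.zeros(n)
    w = np.hanning(21)
    w /= w.sum()
    raw = rng.normal(0.0, 1.0, size=n + 40)
    sm = np.convolve(raw, w, mode="same")[20 : 20 + n]
    s = sm.std()
    return sm * (sd / s) if s > 0 else np.zeros(n)


def generate_night(
    p: NightSimParams,
    night_id: str = "n001",
    subject_id: str = "s01",
    start: datetime | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[NightRecording, float]:
    """Simulate one minute-level night; returns the recording and true CBT."""
    rng = _rng(rng if rng is not None else p.seed)
    n = int(p.duration_min)
    t_min = np.arange(n, dtype=float)

    ta = (
        p.ambient_mean
        + p.ambient_drift * t_min / 60.0
        + _smooth_noise(n, p.ambient_noise_sd, rng)
    )
    ts = skin_from_cbt(p.true_cbt, ta, p.k_true)
    if p.sensor_noise_sd > 0:
        ts = ts + rng.normal(0.0, p.sensor_noise_sd, size=n)

    # warm-up transient: sensor starts cool and equilibrates within ~1 h
    warmup = float(rng.uniform(45.0, 75.0))
    amp = float(rng.uniform(1.0, 2.0))
    ts = ts - amp * np.exp(-t_min / (warmup / 4.0))

    if p.artifact_prob > 0 and rng.random() < p.artifact_prob and n > 90:
        a_start = int(rng.integers(60, n - 20))
        a_len = int(rng.integers(5, 16))
        drop = float(rng.uniform(1.0, 3.0))
        ts[a_start : a_start + a_len] -= drop

    if start is None:
        start = datetime(2024, 1, 1, 23, 0)
    samples = [
        TemperatureSample(start + timedelta(minutes=int(m)), float(s), float(a))
        for m, s, a in zip(t_min, ts, ta)
    ]
    rec = NightRecording(
        night_id=night_id, subject_id=subject_id, date=start.date(), samples=samples
    )
    return rec, p.true_cbt


@dataclass
class Cohort:
    """A study-shaped synthetic dataset.

    ``daily`` is the day-level table (subject_id, date, oral_bbt_c,
    lh_result, menses_onset); ``night_summaries`` carry the estimated-CBT
    channel one night per cycle day; ``truth`` is the generating record
    per cycle.
    """

    daily: pd.DataFrame
    night_summaries: list[NightSummary]
    truth: pd.DataFrame

    def write_csv(self, daily_path, nights_path=None, truth_path=None) -> None:
        df = self.daily.copy()
        if "oral_bbt_c" in df.columns:
            df["oral_bbt_c"] = df["oral_bbt_c"].round(2)
        df.to_csv(daily_path, index=False)
        if nights_path is not None:
            from .io import write_night_summaries

            write_night_summaries(self.night_summaries, nights_path)
        if truth_path is not None:
            self.truth.to_csv(truth_path, index=False)


def generate_cohort(
    n_subjects: int = 26,
    n_cycles: int = 74,
    ovulatory_fraction: float = 60 / 74,
    seed: int | None = None,
    cycle_params: CycleSimParams | None = None,
    bbt_noise_sd: float = 0.15,
    bbt_missing_prob: float = 0.15,
    bbt_offset: float = -0.2,
    start_date: _date = _date(2024, 1, 1),
) -> Cohort:
    """Simulate a full study: subjects, cycles, two temperature channels, LH.

    Exactly ``round(ovulatory_fraction · n_cycles)`` cycles are ovulatory,
    assigned at random positions. Per-subject follicular baselines are
    drawn N(36.48, 0.22). Both channels share each cycle's latent
    temperature profile; the oral-BBT channel gets its own (larger) noise
    and missingness and a level offset, reflecting the looser measurement
    protocol of waking oral readings.
    """
    if n_subjects < 1 or n_cycles < 1:
        raise ValueError("need at least one subject and one cycle")
    rng = _rng(seed)
    base = cycle_params or CycleSimParams()

    n_ov = int(round(ovulatory_fraction * n_cycles))
    labels = np.zeros(n_cycles, dtype=bool)
    labels[:n_ov] = True
    rng.shuffle(labels)

    baselines = rng.normal(
        FOLLICULAR_MEAN, FOLLICULAR_BETWEEN_SUBJECT_SD, size=n_subjects
    )
    subject_of = [i % n_subjects for i in range(n_cycles)]

    daily_rows: list[dict] = []
    summaries: list[NightSummary] = []
    truth_rows: list[dict] = []
    cursor = {i: start_date + timedelta(days=i % 7) for i in range(n_subjects)}
    counter = {i: 0 for i in range(n_subjects)}

    for c in range(n_cycles):
        si = subject_of[c]
        counter[si] += 1
        subject_id = f"s{si + 1:02d}"
        cycle_id = f"{subject_id}-c{counter[si]:02d}"
        length = int(rng.integers(26, 31))
        p = replace(
            base,
            length_days=length,
            ovulatory=bool(labels[c]),
            follicular_mean=float(baselines[si]),
            seed=None,
        )
        series, lh, truth = generate_cycle(p, cycle_id, subject_id, rng=rng)

        # latent profile is shared; re-noise it for the oral-BBT channel
        days = np.arange(1, length + 1)
        latent = np.full(length, p.follicular_mean)
        if truth.ovulatory:
            latent = latent + truth.luteal_shift * _ramp(
                days, truth.ovulation_day, p.shift_ramp_days
            )
        bbt = latent + bbt_offset + rng.normal(0.0, bbt_noise_sd, size=length)
        bbt_seen = rng.random(length) >= bbt_missing_prob

        onset = cursor[si]
        lh_by_day = {r.cycle_day: r.result for r in lh}
        for d in range(1, length + 1):
            day_date = onset + timedelta(days=d - 1)
            daily_rows.append(
                {
                    "subject_id": subject_id,
                    "date": day_date.isoformat(),
                    "oral_bbt_c": float(bbt[d - 1]) if bbt_seen[d - 1] else None,
                    "lh_result": {"positive": "pos", "negative": "neg"}.get(
                        lh_by_day.get(d)
                    ),
                    "menses_onset": 1 if d == 1 else 0,
                }
            )
            if d in series.values:
                summaries.append(
                    NightSummary(
                        night_id=f"{cycle_id}-d{d:02d}",
                        subject_id=subject_id,
                        date=day_date,
                        representative_temp=series.values[d],
                        n_valid=240,
                        n_excluded_ambient=0,
                        n_excluded_artifact=0,
                        window_start=None,
                        window_end=None,
                        quality_flag=QualityFlag.OK,
                    )
                )
        truth_rows.append(
            {
                "cycle_id": cycle_id,
                "subject_id": subject_id,
                "length_days": length,
                "ovulatory": truth.ovulatory,
                "ovulation_day": truth.ovulation_day,
                "luteal_shift": truth.luteal_shift,
            }
        )
        cursor[si] = onset + timedelta(days=length)

    # closing onset so the final cycle of every subject is complete
    for si in range(n_subjects):
        if counter[si] > 0:
            daily_rows.append(
                {
                    "subject_id": f"s{si + 1:02d}",
                    "date": cursor[si].isoformat(),
                    "oral_bbt_c": None,
                    "lh_result": None,
                    "menses_onset": 1,
                }
            )

    daily = pd.DataFrame(daily_rows).sort_values(["subject_id", "date"]).reset_index(
        drop=True
    )
    truth = pd.DataFrame(truth_rows)
    return Cohort(daily=daily, night_summaries=summaries, truth=truth)
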