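"""Core body temperature (CBT) estimation from paired skin/ambient readings.

The estimator is a steady-state heat-flux model: conductive flow from the
body core to the skin (conductivity ``λ1``) equals flow from the skin
through the sensor to the air (``λ2``), giving

    CBT = Ts + K (Ts − Ta),        K = λ2 / λ1

where ``Ts`` is chest skin temperature, ``Ta`` ambient temperature, and
``K`` a dimensionless conductivity ratio. ``K`` is calibrated from data:
under the model, skin temperature is linear in ambient temperature,
``Ts = (K·Ta + CBT) / (1 + K)``, so the slope ``α = K/(1+K)`` of an
ordinary least-squares fit of Ts on Ta yields ``K = α/(1−α)``.

A night recording is reduced to one representative temperature: the first
hour after sensor application is discarded (unstable heat flux), the next
four hours form the analysis window, readings with ambient above skin
temperature are excluded (external heat), step-change artifacts from
sensor displacement are excluded, and the mean estimated CBT over the
remaining minutes is the night's representative value.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from datetime import date as _date
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np

__all__ = [
    "TemperatureSample",
    "ThermalModel",
    "NightRecording",
    "NightSummary",
    "PreprocessConfig",
    "Validity",
    "QualityFlag",
    "DegenerateDesignError",
    "ModelViolationError",
    "NightTooShortError",
    "estimate_cbt",
    "fit_thermal_coefficient",
    "preprocess_night",
    "summarize_night",
]

# Plausibility bounds for raw sensor readings, °C. Out-of-range readings
# are flagged invalid rather than silently dropped.
SKIN_BOUNDS = (15.0, 45.0)
AMBIENT_BOUNDS = (-10.0, 45.0)


class DegenerateDesignError(ValueError):
    """Calibration regression has no information (constant ambient)."""


class ModelViolationError(ValueError):
    """Fitted slope is incompatible with the heat-flux model (α ≥ 1)."""


class NightTooShortError(ValueError):
    """Recording shorter than the warm-up discard period."""


class Validity(enum.Enum):
    """Per-minute disposition of a sample within a night recording."""

    VALID = "valid"
    OUT_OF_WINDOW = "out_of_window"
    INVALID_RANGE = "invalid_range"
    EXCLUDED_AMBIENT = "excluded_ambient"
    EXCLUDED_ARTIFACT = "excluded_artifact"


class QualityFlag(enum.Enum):
    OK = "ok"
    INSUFFICIENT_DATA = "insufficient_data"
    TOO_SHORT = "too_short"


@dataclass(frozen=True)
class TemperatureSample:
    """One minute-level reading: skin temperature ``ts`` and ambient ``ta`` (°C)."""

    t: datetime
    ts: float
    ta: float

    def in_range(self) -> bool:
        return (
            math.isfinite(self.ts)
            and math.isfinite(self.ta)
            and SKIN_BOUNDS[0] <= self.ts <= SKIN_BOUNDS[1]
            and AMBIENT_BOUNDS[0] <= self.ta <= AMBIENT_BOUNDS[1]
        )


@dataclass(frozen=True)
class ThermalModel:
    """Calibrated conductivity ratio K with its regression diagnostics.

    ``alpha`` is the OLS slope of skin on ambient temperature; ``K`` follows
    as ``alpha / (1 − alpha)``. ``clamped`` records that a (noise-driven)
    negative slope was clamped to zero.
    """

    k: float
    alpha: float
    n_points: int
    residual_sd: float
    clamped: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError(f"alpha must lie in [0, 1), got {self.alpha}")
        if self.k < 0:
            raise ValueError(f"K must be non-negative, got {self.k}")


@dataclass
class NightRecording:
    """An ordered minute-level recording for one subject-night."""

    night_id: str
    subject_id: str
    date: _date
    samples: list[TemperatureSample]

    def __post_init__(self) -> None:
        for a, b in zip(self.samples, self.samples[1:]):
            if b.t <= a.t:
                raise ValueError(
                    f"night {self.night_id}: timestamps not strictly increasing at {b.t}"
                )

    @property
    def duration_min(self) -> float:
        if not self.samples:
            return 0.0
        return (self.samples[-1].t - self.samples[0].t).total_seconds() / 60.0 + 1.0


@dataclass
class NightSummary:
    night_id: str
    subject_id: str
    date: _date
    representative_temp: float | None
    n_valid: int
    n_excluded_ambient: int
    n_excluded_artifact: int
    window_start: datetime | None
    window_end: datetime | None
    quality_flag: QualityFlag
    truncated: bool = False


@dataclass(frozen=True)
class PreprocessConfig:
    """Windowing and artifact-rejection settings.

    ``max_step`` bounds the per-minute change of the estimated CBT (°C/min):
    core temperature cannot physiologically move faster, so larger steps
    indicate sensor displacement. ``max_ambient_step`` likewise bounds
    per-minute ambient change. An artifact run ends when the estimate
    returns within ``max_step`` of the last pre-artifact valid value.
    """

    window_discard_min: int = 60
    window_length_min: int = 240
    max_step: float = 0.3
    max_ambient_step: float = 2.0
    min_valid_fraction: float = 0.5


def estimate_cbt(ts, ta, k):
    """Estimated core body temperature ``Ts + K (Ts − Ta)``.

    Accepts scalars or numpy arrays for ``ts``/``ta``; exact arithmetic,
    no rounding.
    """
    k = float(k)
    if not math.isfinite(k):
        raise ValueError("K must be finite")
    if k < 0:
        raise ValueError(f"K must be non-negative, got {k}")
    ts_a = np.asarray(ts, dtype=float)
    ta_a = np.asarray(ta, dtype=float)
    if not (np.all(np.isfinite(ts_a)) and np.all(np.isfinite(ta_a))):
        raise ValueError("temperatures must be finite")
    out = ts_a + k * (ts_a - ta_a)
    if np.isscalar(ts) or out.ndim == 0:
        return float(out)
    return out


def skin_from_cbt(cbt, ta, k):
    """Forward model: skin temperature implied by a core temperature.

    Inverts :func:`estimate_cbt`: ``Ts = (K·Ta + CBT) / (1 + K)``.
    """
    cbt_a = np.asarray(cbt, dtype=float)
    ta_a = np.asarray(ta, dtype=float)
    out = (k * ta_a + cbt_a) / (1.0 + k)
    if out.ndim == 0:
        return float(out)
    return out


def fit_thermal_coefficient(
    pairs: Sequence[TemperatureSample] | tuple[np.ndarray, np.ndarray],
) -> ThermalModel:
    """Calibrate K from paired (skin, ambient) readings.

    ``pairs`` is a sequence of :class:`TemperatureSample` or an ``(ts, ta)``
    array pair. Implausible or non-finite readings are dropped before the
    fit. The slope of the OLS regression of skin on ambient temperature is
    ``α``; ``K = α/(1−α)``. A negative fitted slope is clamped to zero and
    flagged; ``α ≥ 1`` is a model violation and is refused.
    """
    if isinstance(pairs, tuple) and len(pairs) == 2:
        ts = np.asarray(pairs[0], dtype=float)
        ta = np.asarray(pairs[1], dtype=float)
    else:
        valid = [s for s in pairs if s.in_range()]
        ts = np.array([s.ts for s in valid], dtype=float)
        ta = np.array([s.ta for s in valid], dtype=float)
    keep = (
        np.isfinite(ts)
        & np.isfinite(ta)
        & (ts >= SKIN_BOUNDS[0])
        & (ts <= SKIN_BOUNDS[1])
        & (ta >= AMBIENT_BOUNDS[0])
        & (ta <= AMBIENT_BOUNDS[1])
    )
    ts, ta = ts[keep], ta[keep]
    n = ts.size
    if n < 10:
        raise ValueError(f"need at least 10 valid calibration pairs, got {n}")
    if np.var(ta) == 0:
        raise DegenerateDesignError("ambient temperature is constant; slope undefined")

    # OLS slope of Ts on Ta
    alpha, intercept = np.polyfit(ta, ts, 1)
    resid = ts - (alpha * ta + intercept)
    residual_sd = float(np.sqrt(np.sum(resid**2) / max(n - 2, 1)))
    clamped = False
    if alpha >= 1.0:
        raise ModelViolationError(
            f"fitted slope α={alpha:.4f} ≥ 1: skin cannot track ambient this "
            "strongly under the heat-flux model"
        )
    if alpha < 0.0:
        alpha = 0.0
        clamped = True
    k = alpha / (1.0 - alpha)
    return ThermalModel(
        k=float(k),
        alpha=float(alpha),
        n_points=int(n),
        residual_sd=residual_sd,
        clamped=clamped,
    )


def preprocess_night(
    rec: NightRecording,
    cfg: PreprocessConfig | None = None,
    model: ThermalModel | None = None,
) -> list[tuple[TemperatureSample, Validity]]:
    """Assign a validity flag to every sample of a night recording.

    The first ``window_discard_min`` minutes are out-of-window (sensor
    warm-up), the following ``window_length_min`` minutes form the analysis
    window, and anything after is out-of-window. Within the window a sample
    is flagged, in order of precedence: invalid_range (implausible or
    non-finite reading), excluded_ambient (Ta > Ts), excluded_artifact
    (step-change rule, see :class:`PreprocessConfig`), else valid.

    Raises :class:`NightTooShortError` for recordings shorter than the
    discard period. A recording that covers the discard period but not the
    full window is processed on the truncated window.
    """
    cfg = cfg or PreprocessConfig()
    if not rec.samples:
        raise ValueError("empty recording")
    if rec.duration_min < cfg.window_discard_min:
        raise NightTooShortError(
            f"night {rec.night_id}: {rec.duration_min:.0f} min < "
            f"{cfg.window_discard_min} min warm-up discard"
        )
    k = model.k if model is not None else 0.0

    start = rec.samples[0].t
    w_start = start + timedelta(minutes=cfg.window_discard_min)
    w_end = w_start + timedelta(minutes=cfg.window_length_min)

    flags: list[tuple[TemperatureSample, Validity]] = []
    last_t: datetime | None = None
    last_cbt = last_ta = anchor_cbt = 0.0
    in_artifact = False
    for s in rec.samples:
        if s.t < w_start or s.t >= w_end:
            flags.append((s, Validity.OUT_OF_WINDOW))
            continue
        if not s.in_range():
            flags.append((s, Validity.INVALID_RANGE))
            continue
        if s.ta > s.ts:
            flags.append((s, Validity.EXCLUDED_AMBIENT))
            continue
        cbt = estimate_cbt(s.ts, s.ta, k)
        if last_t is None:
            flags.append((s, Validity.VALID))
            last_t, last_cbt, last_ta = s.t, cbt, s.ta
            continue
        if in_artifact:
            # run ends when the estimate returns near the pre-artifact level
            if abs(cbt - anchor_cbt) <= cfg.max_step:
                in_artifact = False
                flags.append((s, Validity.VALID))
                last_t, last_cbt, last_ta = s.t, cbt, s.ta
            else:
                flags.append((s, Validity.EXCLUDED_ARTIFACT))
            continue
        gap_min = max((s.t - last_t).total_seconds() / 60.0, 1.0)
        if (
            abs(cbt - last_cbt) > cfg.max_step * gap_min
            or abs(s.ta - last_ta) > cfg.max_ambient_step * gap_min
        ):
            in_artifact = True
            anchor_cbt = last_cbt
            flags.append((s, Validity.EXCLUDED_ARTIFACT))
        else:
            flags.append((s, Validity.VALID))
            last_t, last_cbt, last_ta = s.t, cbt, s.ta
    return flags


def summarize_night(
    rec: NightRecording,
    model: ThermalModel,
    cfg: PreprocessConfig | None = None,
) -> NightSummary:
    """Reduce a night to its representative temperature.

    The representative temperature is the arithmetic mean of the estimated
    CBT over valid in-window minutes. If fewer than
    ``cfg.min_valid_fraction`` of the window's minutes are valid, the night
    is flagged insufficient_data and the representative temperature is
    missing.
    """
    cfg = cfg or PreprocessConfig()
    base = dict(night_id=rec.night_id, subject_id=rec.subject_id, date=rec.date)
    try:
        flags = preprocess_night(rec, cfg, model)
    except NightTooShortError:
        return NightSummary(
            **base,
            representative_temp=None,
            n_valid=0,
            n_excluded_ambient=0,
            n_excluded_artifact=0,
            window_start=None,
            window_end=None,
            quality_flag=QualityFlag.TOO_SHORT,
        )
    start = rec.samples[0].t
    w_start = start + timedelta(minutes=cfg.window_discard_min)
    w_end = w_start + timedelta(minutes=cfg.window_length_min)
    # nominal window length in minutes, shortened if the recording ends early
    window_min = min(
        float(cfg.window_length_min), rec.duration_min - cfg.window_discard_min
    )
    truncated = window_min < cfg.window_length_min

    valid = [s for s, v in flags if v is Validity.VALID]
    n_amb = sum(1 for _, v in flags if v is Validity.EXCLUDED_AMBIENT)
    n_art = sum(1 for _, v in flags if v is Validity.EXCLUDED_ARTIFACT)
    n_valid = len(valid)

    if window_min <= 0 or n_valid == 0 or n_valid / window_min < cfg.min_valid_fraction:
        return NightSummary(
            **base,
            representative_temp=None,
            n_valid=n_valid,
            n_excluded_ambient=n_amb,
            n_excluded_artifact=n_art,
            window_start=w_start,
            window_end=w_end,
            quality_flag=QualityFlag.INSUFFICIENT_DATA,
            truncated=truncated,
        )
    cbt = estimate_cbt(
        np.array([s.ts for s in valid]), np.array([s.ta for s in valid]), model.k
    )
    return NightSummary(
        **base,
        representative_temp=float(np.mean(cbt)),
        n_valid=n_valid,
        n_excluded_ambient=n_amb,
        n_excluded_artifact=n_art,
        window_start=w_start,
        window_end=w_end,
        quality_flag=QualityFlag.OK,
        truncated=truncated,
    )
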