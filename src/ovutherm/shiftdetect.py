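"""Biphasic temperature-shift detection: the three-over-six rule.

A post-ovulatory rise is declared at cycle day ``d`` when the three
consecutive recorded measurements starting at ``d`` are each at least
0.2 °C above the maximum of the six calendar days before ``d`` (the
reference window). The reference window is evaluable when at least four of
its six days are recorded. Two mutually exclusive exceptions soften the
rule:

* **fourth-measurement exception** — the first two rising values clear the
  reference maximum by ≥ 0.2 °C but the third is above the maximum by less
  than 0.2 °C; the next recorded measurement (the fourth) confirms the
  shift if it exceeds the reference maximum by any margin.
* **disregard exception** — exactly one of the three rising values drops
  to or below the *mean* of the reference window; it is disregarded and
  replaced by the next recorded measurement, and the shift is confirmed if
  the replacement-completed third value is at least 0.2 °C above the
  reference mean (the two retained values must still clear the reference
  maximum by ≥ 0.2 °C).

Only shifts whose onset falls in the last 14 days of the cycle classify it
as biphasic; a cycle without such a shift is monophasic (read as
anovulatory by the temperature method). Temperatures are rounded to
0.01 °C before rule evaluation and comparisons carry a small float guard.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean
from typing import Iterable, Sequence

from .cycles import DailySeries

__all__ = [
    "ShiftDetection",
    "CycleClassification",
    "detect_shifts",
    "classify_cycle",
    "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = 0.2

# minimum series length for the rule to be evaluable at all
MIN_SERIES_DAYS = 10

# shifts are accepted only in the final ACCEPT_WINDOW_DAYS of the cycle
ACCEPT_WINDOW_DAYS = 14

_EPS = 1e-9


def _ge(a: float, b: float) -> bool:
    """a ≥ b with a float guard ('at least')."""
    return a >= b - _EPS


def _gt(a: float, b: float) -> bool:
    """a > b, strict ('exceeds')."""
    return a > b + _EPS


@dataclass(frozen=True)
class ShiftDetection:
    """A confirmed temperature shift at ``onset_day``.

    ``rising_days`` are the cycle days whose values form the confirmed
    rising sequence (three days for the base rule, four when an exception
    was invoked). ``n_reference`` counts the recorded days among the six
    reference days.
    """

    onset_day: int
    rule_variant: str  # base | exception_fourth | exception_disregard
    reference_max: float
    reference_mean: float
    n_reference: int
    rising_days: tuple[int, ...]


@dataclass
class CycleClassification:
    cycle_id: str
    source: str
    status: str  # biphasic | monophasic
    accepted_shift: ShiftDetection | None
    all_detections: list[ShiftDetection]
    evaluable: bool = True


def _evaluate_candidate(
    vals: dict[int, float], d: int, length: int, thr: float
) -> ShiftDetection | None:
    ref_days = range(d - 6, d)
    ref_vals = [vals[x] for x in ref_days if x in vals]
    if len(ref_vals) < 4:
        return None
    rmax = max(ref_vals)
    rmean = mean(ref_vals)

    # three consecutive recorded measurements; a missing day breaks the run
    days3 = (d, d + 1, d + 2)
    if days3[-1] > length or any(x not in vals for x in days3):
        return None
    r = [vals[x] for x in days3]

    if all(_ge(x, rmax + thr) for x in r):
        return ShiftDetection(d, "base", rmax, rmean, len(ref_vals), days3)

    def next_recorded(after: int) -> int | None:
        for x in range(after + 1, length + 1):
            if x in vals:
                return x
        return None

    # fourth-measurement exception: pattern-matching it forecloses the
    # disregard exception (mutual exclusivity by first match)
    if (
        _ge(r[0], rmax + thr)
        and _ge(r[1], rmax + thr)
        and _gt(r[2], rmax)
        and not _ge(r[2], rmax + thr)
    ):
        d4 = next_recorded(days3[-1])
        if d4 is not None and _gt(vals[d4], rmax):
            return ShiftDetection(
                d, "exception_fourth", rmax, rmean, len(ref_vals), days3 + (d4,)
            )
        return None

    # disregard exception: exactly one of the three at or below the
    # reference mean is dropped and replaced by the next recorded value
    low = [i for i, x in enumerate(r) if _ge(rmean, x)]
    if len(low) == 1:
        kept = [x for i, x in enumerate(r) if i != low[0]]
        d4 = next_recorded(days3[-1])
        if (
            d4 is not None
            and all(_ge(x, rmax + thr) for x in kept)
            and _ge(vals[d4], rmean + thr)
        ):
            kept_days = tuple(x for i, x in enumerate(days3) if i != low[0]) + (d4,)
            return ShiftDetection(
                d, "exception_disregard", rmax, rmean, len(ref_vals), kept_days
            )
    return None


def detect_shifts(
    series: DailySeries,
    threshold: float = DEFAULT_THRESHOLD,
    exclude_days: Iterable[int] = (),
) -> list[ShiftDetection]:
    """All confirmed shift detections of a daily series, in onset order.

    ``exclude_days`` is an optional externally annotated mask (e.g. days
    with fever); those days are treated as missing. Series shorter than 10
    days are not evaluable and yield no detections. Deterministic: no
    randomness anywhere.
    """
    if series.length_days < MIN_SERIES_DAYS:
        return []
    excluded = set(exclude_days)
    vals = {
        d: round(v, 2) for d, v in series.values.items() if d not in excluded
    }
    out: list[ShiftDetection] = []
    for d in range(7, series.length_days + 1):
        det = _evaluate_candidate(vals, d, series.length_days, threshold)
        if det is not None:
            out.append(det)
    return out


def classify_cycle(
    series: DailySeries,
    detections: Sequence[ShiftDetection] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    exclude_days: Iterable[int] = (),
    prefer: str = "earliest",
) -> CycleClassification:
    """Classify a cycle as biphasic or monophasic.

    Only detections whose onset lies in the last 14 calendar days of the
    cycle (days ``length−13 .. length``) can be accepted; earlier shifts
    are retained in ``all_detections`` but never accepted. With several
    in-window detections the earliest is accepted by default
    (``prefer='latest'`` flips the tie-break).
    """
    if prefer not in ("earliest", "latest"):
        raise ValueError("prefer must be 'earliest' or 'latest'")
    if detections is None:
        detections = detect_shifts(series, threshold, exclude_days)
    evaluable = series.length_days >= MIN_SERIES_DAYS
    window_lo = series.length_days - (ACCEPT_WINDOW_DAYS - 1)
    in_window = [d for d in detections if d.onset_day >= window_lo]
    accepted = None
    if in_window:
        accepted = in_window[0] if prefer == "earliest" else in_window[-1]
    return CycleClassification(
        cycle_id=series.cycle_id,
        source=series.source,
        status="biphasic" if accepted is not None else "monophasic",
        accepted_shift=accepted,
        all_detections=list(detections),
        evaluable=evaluable,
    )
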