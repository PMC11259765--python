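"""Day-level cycle assembly, LH labelling, and study inclusion filters.

A menstrual cycle runs from one menses onset to the day before the next;
cycle day 1 is the onset date. Each cycle carries one daily temperature
series per source (estimated CBT from night summaries, oral BBT from
morning readings) and a sequence of urine LH test results. A cycle with at
least one positive LH test is labelled ovulatory; one with only negative
recorded results is anovulatory; one with no recorded result is
unlabelled. Unlabelled cycles, and cycles where any available temperature
source is more than 30% missing, are excluded from accuracy analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from datetime import date as _date
from datetime import timedelta
from typing import Iterable, Sequence

import pandas as pd

from .heatflux import NightSummary

__all__ = [
    "LHResult",
    "DailySeries",
    "CycleRecord",
    "label_ovulatory",
    "apply_inclusion_filters",
    "assemble_cycles",
    "SOURCE_ESTIMATED_CBT",
    "SOURCE_ORAL_BBT",
]

SOURCE_ESTIMATED_CBT = "estimated_cbt"
SOURCE_ORAL_BBT = "oral_bbt"

# fraction of missing temperature days above which a cycle is excluded
MAX_MISSING_FRACTION = 0.30

# a 6-day reference window + 3 rising days + a 14-day acceptance tail need
# at least this many days to be meaningfully evaluable
MIN_EVALUABLE_DAYS = 15


@dataclass(frozen=True)
class LHResult:
    """One urine LH test: ``positive``, ``negative`` or ``missing``."""

    cycle_day: int
    result: str

    def __post_init__(self) -> None:
        if self.cycle_day < 1:
            raise ValueError("cycle_day must be ≥ 1")
        if self.result not in ("positive", "negative", "missing"):
            raise ValueError(f"unknown LH result {self.result!r}")


@dataclass
class DailySeries:
    """One representative temperature per cycle day, with missingness.

    ``values`` maps cycle day (1-based) to °C; absent keys are missing
    days. ``source`` records whether the values are estimated CBT or oral
    BBT.
    """

    cycle_id: str
    subject_id: str
    length_days: int
    values: dict[int, float]
    source: str

    def __post_init__(self) -> None:
        bad = [d for d in self.values if not 1 <= d <= self.length_days]
        if bad:
            raise ValueError(f"cycle days {bad} outside 1..{self.length_days}")
        self.values = {
            d: v for d, v in self.values.items() if v is not None and math.isfinite(v)
        }

    @property
    def n_missing(self) -> int:
        return self.length_days - len(self.values)

    @property
    def missing_fraction(self) -> float:
        return self.n_missing / self.length_days

    @property
    def long_enough(self) -> bool:
        return self.length_days >= MIN_EVALUABLE_DAYS


@dataclass
class CycleRecord:
    cycle_id: str
    subject_id: str
    length_days: int
    series: dict[str, DailySeries]
    lh: list[LHResult]
    label: str = "unlabelled"
    included: bool | None = None
    exclusion_reason: str | None = None


def label_ovulatory(lh: Sequence[LHResult]) -> str:
    """Label a cycle from its LH results.

    Any positive result → ``ovulatory``; at least one recorded result and
    all negative → ``anovulatory``; nothing recorded → ``unlabelled``.
    Order-free and robust to duplicated negatives.
    """
    recorded = [r for r in lh if r.result != "missing"]
    if any(r.result == "positive" for r in recorded):
        return "ovulatory"
    if recorded:
        return "anovulatory"
    return "unlabelled"


def apply_inclusion_filters(cycle: CycleRecord) -> CycleRecord:
    """Apply the study's exclusion rules; idempotent.

    Excluded with reason ``missing_lh`` when the cycle is unlabelled, and
    with ``missing_temps`` when any available temperature source has more
    than 30% of its days missing. The whole cycle is excluded when either
    source fails, keeping the paired method comparison on a common set.
    """
    out = replace(cycle)
    if out.label == "unlabelled":
        out.included = False
        out.exclusion_reason = "missing_lh"
        return out
    for src, series in out.series.items():
        if series.missing_fraction > MAX_MISSING_FRACTION:
            out.included = False
            out.exclusion_reason = "missing_temps"
            return out
    out.included = True
    out.exclusion_reason = None
    return out


def _lh_from_value(v) -> str | None:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    s = str(v).strip().lower()
    if s in ("pos", "positive", "1", "true"):
        return "positive"
    if s in ("neg", "negative", "0", "false"):
        return "negative"
    if s in ("", "nan", "missing"):
        return None
    raise ValueError(f"unrecognised LH value {v!r}")


def assemble_cycles(
    daily: pd.DataFrame,
    night_summaries: Iterable[NightSummary] | None = None,
) -> list[CycleRecord]:
    """Build labelled cycles from a day-level table and night summaries.

    ``daily`` needs columns ``subject_id``, ``date``, ``menses_onset``
    (0/1) and optionally ``oral_bbt_c`` and ``lh_result``. Consecutive
    onsets delimit cycles; readings are mapped to cycle days by calendar
    date. A night is assigned to the cycle day of its start date's evening.
    Night summaries without a representative temperature (too short,
    insufficient data) leave that day missing.

    Returns one :class:`CycleRecord` per completed cycle, already labelled
    and passed through :func:`apply_inclusion_filters`.
    """
    df = daily.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.date
    if df.duplicated(["subject_id", "date"]).any():
        raise ValueError("duplicate (subject_id, date) rows in day-level table")

    nights_by_subject: dict[str, dict[_date, float]] = {}
    for ns in night_summaries or ():
        if ns.representative_temp is not None:
            nights_by_subject.setdefault(str(ns.subject_id), {})[ns.date] = (
                ns.representative_temp
            )

    cycles: list[CycleRecord] = []
    for subject_id, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("date")
        onsets = sorted(grp.loc[grp["menses_onset"] == 1, "date"])
        if len(onsets) != len(set(onsets)):
            raise ValueError(f"subject {subject_id}: duplicate menses onsets")
        by_date = grp.set_index("date")
        night_map = nights_by_subject.get(str(subject_id), {})
        for i, (start, nxt) in enumerate(zip(onsets, onsets[1:]), start=1):
            length = (nxt - start).days
            cycle_id = f"{subject_id}-c{i:02d}"
            bbt_vals: dict[int, float] = {}
            cbt_vals: dict[int, float] = {}
            lh: list[LHResult] = []
            for d in range(1, length + 1):
                day_date = start + timedelta(days=d - 1)
                if day_date in night_map:
                    cbt_vals[d] = night_map[day_date]
                if day_date in by_date.index:
                    row = by_date.loc[day_date]
                    bbt = row.get("oral_bbt_c")
                    if bbt is not None and not pd.isna(bbt):
                        bbt_vals[d] = float(bbt)
                    res = _lh_from_value(row.get("lh_result"))
                    if res is not None:
                        lh.append(LHResult(cycle_day=d, result=res))
            series: dict[str, DailySeries] = {}
            if night_map:
                series[SOURCE_ESTIMATED_CBT] = DailySeries(
                    cycle_id, str(subject_id), length, cbt_vals, SOURCE_ESTIMATED_CBT
                )
            if "oral_bbt_c" in df.columns:
                series[SOURCE_ORAL_BBT] = DailySeries(
                    cycle_id, str(subject_id), length, bbt_vals, SOURCE_ORAL_BBT
                )
            rec = CycleRecord(
                cycle_id=cycle_id,
                subject_id=str(subject_id),
                length_days=length,
                series=series,
                lh=lh,
                label=label_ovulatory(lh),
            )
            cycles.append(apply_inclusion_filters(rec))
    return cycles
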