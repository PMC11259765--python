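"""CSV dialects shared by the library, CLI and examples.

Minute-level input: one row per minute with columns ``subject_id``,
``night_id``, ``timestamp`` (ISO-8601), ``skin_temp_c``, ``ambient_temp_c``.
Night-summary output: one row per night. Day-level input: one row per
subject-day with ``subject_id``, ``date``, optional ``oral_bbt_c`` and
``lh_result`` (pos/neg), and ``menses_onset`` (0/1). Temperatures are
written rounded to 0.01 °C; full precision is kept internally.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .heatflux import NightRecording, NightSummary, QualityFlag, TemperatureSample

__all__ = [
    "read_minute_csv",
    "write_night_summaries",
    "read_night_summaries",
    "read_daylevel_csv",
]


def read_minute_csv(path) -> list[NightRecording]:
    """Load minute-level recordings, one :class:`NightRecording` per night_id."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    required = {"subject_id", "night_id", "timestamp", "skin_temp_c", "ambient_temp_c"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"minute-level CSV missing columns: {sorted(missing)}")
    recs = []
    for night_id, grp in df.groupby("night_id", sort=True):
        grp = grp.sort_values("timestamp")
        samples = [
            TemperatureSample(ts.to_pydatetime(), float(s), float(a))
            for ts, s, a in zip(
                grp["timestamp"], grp["skin_temp_c"], grp["ambient_temp_c"]
            )
        ]
        recs.append(
            NightRecording(
                night_id=str(night_id),
                subject_id=str(grp["subject_id"].iloc[0]),
                date=samples[0].t.date(),
                samples=samples,
            )
        )
    return recs


def write_night_summaries(summaries: Iterable[NightSummary], path) -> None:
    rows = [
        {
            "night_id": s.night_id,
            "subject_id": s.subject_id,
            "date": s.date.isoformat(),
            "representative_temp_c": (
                None
                if s.representative_temp is None
                else round(s.representative_temp, 2)
            ),
            "n_valid": s.n_valid,
            "n_excluded_ambient": s.n_excluded_ambient,
            "n_excluded_artifact": s.n_excluded_artifact,
            "quality_flag": s.quality_flag.value,
        }
        for s in summaries
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_night_summaries(path) -> list[NightSummary]:
    df = pd.read_csv(path, parse_dates=["date"])
    out = []
    for _, r in df.iterrows():
        temp = r.get("representative_temp_c")
        out.append(
            NightSummary(
                night_id=str(r["night_id"]),
                subject_id=str(r["subject_id"]),
                date=r["date"].date(),
                representative_temp=None if pd.isna(temp) else float(temp),
                n_valid=int(r.get("n_valid", 0)),
                n_excluded_ambient=int(r.get("n_excluded_ambient", 0)),
                n_excluded_artifact=int(r.get("n_excluded_artifact", 0)),
                window_start=None,
                window_end=None,
                quality_flag=QualityFlag(r.get("quality_flag", "ok")),
            )
        )
    return out


def read_daylevel_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "date", "menses_onset"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"day-level CSV missing columns: {sorted(missing)}")
    return df
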