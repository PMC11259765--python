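from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np
import pytest

from ovutherm.cycles import SOURCE_ESTIMATED_CBT, DailySeries
from ovutherm.heatflux import NightRecording, TemperatureSample


def make_series(
    values, length=None, cycle_id="c01", subject_id="s01", source=SOURCE_ESTIMATED_CBT
) -> DailySeries:
    """Build a DailySeries from a 1-based list (None = missing) or a dict."""
    if isinstance(values, dict):
        vals = dict(values)
        n = length or max(vals)
    else:
        vals = {d: v for d, v in enumerate(values, start=1) if v is not None}
        n = length or len(values)
    return DailySeries(
        cycle_id=cycle_id,
        subject_id=subject_id,
        length_days=n,
        values=vals,
        source=source,
    )


def make_night(
    ts, ta, start=datetime(2024, 1, 1, 23, 0), night_id="n01", subject_id="s01"
) -> NightRecording:
    """Build a NightRecording from per-minute skin/ambient arrays."""
    ts = np.asarray(ts, dtype=float)
    ta = np.broadcast_to(np.asarray(ta, dtype=float), ts.shape)
    samples = [
        TemperatureSample(start + timedelta(minutes=i), float(s), float(a))
        for i, (s, a) in enumerate(zip(ts, ta))
    ]
    return NightRecording(night_id, subject_id, start.date(), samples)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
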