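"""The three-over-six rule on hand-sized daily series.

Four small series walk through the rule: the base case, the two
exceptions, and the last-14-days acceptance filter.
"""

from ovutherm.cycles import DailySeries
from ovutherm.shiftdetect import classify_cycle, detect_shifts


def series(vals, length=None):
    values = {d: v for d, v in enumerate(vals, start=1) if v is not None}
    return DailySeries("demo", "s01", length or len(vals), values, "estimated_cbt")


cases = {
    "base rule": series([36.2] * 6 + [36.5] * 6),
    "fourth-measurement exception": series(
        [36.2] * 6 + [36.5, 36.5, 36.35, 36.25], length=12
    ),
    "disregard exception": series([36.2] * 6 + [36.5, 36.15, 36.5, 36.45], length=12),
    "early shift only (outside last 14 days)": series(
        [36.2] * 9 + [36.5] * 3 + [36.2] * 16, length=28
    ),
}

for name, s in cases.items():
    dets = detect_shifts(s)
    cls = classify_cycle(s, dets)
    onsets = [(d.onset_day, d.rule_variant) for d in dets]
    accepted = None if cls.accepted_shift is None else cls.accepted_shift.onset_day
    print(f"{name:42s} detections={onsets or '[]'}  ->  {cls.status}"
          f"{f' (onset day {accepted})' if accepted else ''}")

print(
    "\nA shift needs 3 consecutive days ≥ 0.2 °C above the max of the 6\n"
    "previous days; only shifts with onset in the cycle's last 14 days make\n"
    "the cycle biphasic (read as ovulatory)."
)
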