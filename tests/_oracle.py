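"""Literal brute-force re-statement of the three-over-six rule.

Written independently of ovutherm.shiftdetect, straight from the rule's
textual definition, as the reference the implementation is checked
against. Works on a plain list of per-day values (None = missing),
1-based days.
"""

from __future__ import annotations

EPS = 1e-9


def _recorded_days_after(values, day):
    return [d for d in range(day + 1, len(values) + 1) if values[d - 1] is not None]


def oracle_detect(values: list, threshold: float = 0.2) -> list[tuple[int, str]]:
    """All confirmed (onset_day, variant) detections, literal evaluation."""
    L = len(values)
    if L < 10:
        return []
    vals = [None if v is None else round(v, 2) for v in values]
    hits = []
    for onset in range(7, L + 1):
        # the six calendar days before the onset; at least 4 recorded
        ref = [vals[d - 1] for d in range(onset - 6, onset) if vals[d - 1] is not None]
        if len(ref) < 4:
            continue
        ref_max = max(ref)
        ref_mean = sum(ref) / len(ref)
        # three consecutive recorded measurements, no missing day between
        if onset + 2 > L:
            continue
        triple = [vals[onset - 1], vals[onset], vals[onset + 1]]
        if any(v is None for v in triple):
            continue

        if all(v >= ref_max + threshold - EPS for v in triple):
            hits.append((onset, "base"))
            continue

        # exception 1: third higher but by less than the threshold;
        # a fourth measurement exceeding the reference maximum confirms
        first_two_ok = all(v >= ref_max + threshold - EPS for v in triple[:2])
        third_partial = (triple[2] > ref_max + EPS) and (
            triple[2] < ref_max + threshold - EPS
        )
        if first_two_ok and third_partial:
            later = _recorded_days_after(vals, onset + 2)
            if later and vals[later[0] - 1] > ref_max + EPS:
                hits.append((onset, "exception_fourth"))
            # exceptions are mutually exclusive: stop here either way
            continue

        # exception 2: exactly one of the three drops to or below the
        # reference mean; it is disregarded and replaced by the next
        # recorded measurement, which must be >= mean + threshold, the
        # two retained values still clearing max + threshold
        at_or_below = [i for i, v in enumerate(triple) if v <= ref_mean + EPS]
        if len(at_or_below) == 1:
            retained = [v for i, v in enumerate(triple) if i != at_or_below[0]]
            later = _recorded_days_after(vals, onset + 2)
            if (
                later
                and all(v >= ref_max + threshold - EPS for v in retained)
                and vals[later[0] - 1] >= ref_mean + threshold - EPS
            ):
                hits.append((onset, "exception_disregard"))
    return hits


def oracle_classify(values: list, threshold: float = 0.2) -> tuple[str, int | None]:
    """(status, accepted onset): earliest detection in the last 14 days."""
    L = len(values)
    for onset, _ in oracle_detect(values, threshold):
        if onset >= L - 13:
            return "biphasic", onset
    return "monophasic", None
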