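"""Diagnostic accuracy of temperature-based ovulation calls vs the LH reference.

A biphasic call is the positive test outcome; an ovulatory label by urine
LH test is the positive reference. The 2×2 contingency table yields
sensitivity, specificity, predictive values and the F1 score. Two methods
evaluated on the same cycles are compared with McNemar's paired test on
their discordant correctness, their biphasic proportions with a 2×2 χ²
test, and paired continuous measurements with the repeated-measures
correlation coefficient (the common within-subject slope's correlation,
estimated by analysis of covariance with per-subject intercepts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable",
    "DiagnosticReport",
    "PairedComparison",
    "ProportionTestResult",
    "RmCorrResult",
    "build_contingency",
    "compute_metrics",
    "mcnemar_test",
    "mcnemar_from_counts",
    "proportion_test",
    "rmcorr",
]

# exact binomial McNemar below this many discordant pairs, χ² with
# continuity correction at or above it
EXACT_MCNEMAR_MAX_DISCORDANT = 25


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 counts: positive call = biphasic, positive reference = ovulatory."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.total == 0:
            raise ValueError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class DiagnosticReport:
    """Accuracy metrics in percent (F1 as a fraction); ``None`` = undefined.

    A metric is undefined when its denominator is zero (e.g. specificity
    with no reference-negative cycles).
    """

    table: ContingencyTable
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    f1: float | None

    def rounded(self) -> dict[str, float | None]:
        """Metrics at reporting precision (2 decimals)."""
        out = {}
        for name in ("sensitivity", "specificity", "ppv", "npv", "f1"):
            v = getattr(self, name)
            out[name] = None if v is None else round(v, 2)
        return out


@dataclass(frozen=True)
class PairedComparison:
    b: int  # method A correct, method B wrong
    c: int  # method B correct, method A wrong
    statistic: float
    p_value: float
    method: str  # exact_binomial | chi2_cc


@dataclass(frozen=True)
class ProportionTestResult:
    statistic: float
    p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class RmCorrResult:
    """Repeated-measures correlation with Fisher-z 95% CI."""

    r_rm: float
    df: int
    ci_low: float
    ci_high: float
    p_value: float
    n_pairs: int
    n_subjects: int


def build_contingency(
    calls: Mapping[str, str], labels: Mapping[str, str]
) -> ContingencyTable:
    """Cross-tabulate per-cycle biphasic/monophasic calls against LH labels.

    ``calls`` and ``labels`` must cover the same cycles; labels must be
    ovulatory or anovulatory (exclude unlabelled cycles upstream).
    """
    if set(calls) != set(labels):
        raise ValueError("calls and labels cover different cycle sets")
    if not calls:
        raise ValueError("no cycles to score")
    tp = fp = tn = fn = 0
    for cyc, call in calls.items():
        lab = labels[cyc]
        if call not in ("biphasic", "monophasic"):
            raise ValueError(f"unknown call {call!r} for cycle {cyc}")
        if lab not in ("ovulatory", "anovulatory"):
            raise ValueError(f"unknown label {lab!r} for cycle {cyc}")
        pos_call = call == "biphasic"
        pos_ref = lab == "ovulatory"
        if pos_call and pos_ref:
            tp += 1
        elif pos_call:
            fp += 1
        elif pos_ref:
            fn += 1
        else:
            tn += 1
    return ContingencyTable(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int, scale: float) -> float | None:
    return None if den == 0 else scale * num / den


def compute_metrics(ct: ContingencyTable) -> DiagnosticReport:
    """Sensitivity, specificity, PPV, NPV (percent) and F1 (fraction).

    Standard definitions: sensitivity = tp/(tp+fn), specificity =
    tn/(tn+fp), PPV = tp/(tp+fp), NPV = tn/(tn+fn), F1 =
    2·tp/(2·tp+fp+fn). Any metric with a zero denominator is ``None``.
    """
    return DiagnosticReport(
        table=ct,
        sensitivity=_ratio(ct.tp, ct.tp + ct.fn, 100.0),
        specificity=_ratio(ct.tn, ct.tn + ct.fp, 100.0),
        ppv=_ratio(ct.tp, ct.tp + ct.fp, 100.0),
        npv=_ratio(ct.tn, ct.tn + ct.fn, 100.0),
        f1=_ratio(2 * ct.tp, 2 * ct.tp + ct.fp + ct.fn, 1.0),
    )


def mcnemar_from_counts(b: int, c: int, method: str = "auto") -> PairedComparison:
    """McNemar's test from discordant counts.

    ``method='auto'``: exact two-sided binomial when b+c < 25, otherwise χ²
    with continuity correction, (|b−c|−1)²/(b+c), on 1 df. Either variant
    can be forced with ``'exact_binomial'`` or ``'chi2_cc'``. No
    discordance gives p = 1.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    if method not in ("auto", "exact_binomial", "chi2_cc"):
        raise ValueError(f"unknown method {method!r}")
    n = b + c
    if n == 0:
        return PairedComparison(b, c, 0.0, 1.0, "exact_binomial")
    if method == "exact_binomial" or (
        method == "auto" and n < EXACT_MCNEMAR_MAX_DISCORDANT
    ):
        p = min(1.0, 2.0 * stats.binom.cdf(min(b, c), n, 0.5))
        return PairedComparison(b, c, float(min(b, c)), float(p), "exact_binomial")
    stat = (abs(b - c) - 1.0) ** 2 / n
    p = float(stats.chi2.sf(stat, df=1))
    return PairedComparison(b, c, float(stat), p, "chi2_cc")


def mcnemar_test(
    correct_a: Mapping[str, bool], correct_b: Mapping[str, bool]
) -> PairedComparison:
    """Paired accuracy comparison of two methods on the same cycles.

    ``correct_*`` map each cycle to whether the method's call agreed with
    the LH label. b counts cycles where A is correct and B wrong; c the
    reverse.
    """
    if set(correct_a) != set(correct_b):
        raise ValueError("methods evaluated on different cycle sets")
    b = sum(1 for k in correct_a if correct_a[k] and not correct_b[k])
    c = sum(1 for k in correct_a if correct_b[k] and not correct_a[k])
    return mcnemar_from_counts(b, c)


def proportion_test(k1: int, n1: int, k2: int, n2: int) -> ProportionTestResult:
    """χ² test (no continuity correction) of two proportions k1/n1 vs k2/n2."""
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0 or not 0 <= k <= n:
            raise ValueError("need 0 ≤ k ≤ n with n > 0")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if np.any(table.sum(axis=0) == 0):
        # both groups all-success or all-failure: margins degenerate
        return ProportionTestResult(math.nan, math.nan, degenerate=True)
    res = stats.chi2_contingency(table, correction=False)
    return ProportionTestResult(float(res.statistic), float(res.pvalue))


def rmcorr(
    subjects: Sequence, x: Sequence[float], y: Sequence[float]
) -> RmCorrResult:
    """Repeated-measures correlation: the common within-subject association.

    Fits the ANCOVA model y ~ subject-intercepts + common-slope·x. With
    within-subject-centred vectors xc, yc the common slope is
    Σ(xc·yc)/Σ(xc²); the coefficient is

        r_rm = sign(slope) · sqrt(SS_x / (SS_x + SS_error)),

    where SS_x is the sum of squares explained by x given the subject
    intercepts, on df = n_pairs − n_subjects − 1. The p-value is from the
    t distribution on df; the 95% CI uses the Fisher z transform with
    standard error 1/sqrt(df − 1).

    Requires ≥ 2 subjects with ≥ 2 pairs each and within-subject variation
    in x.
    """
    subj = np.asarray(subjects)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (subj.size == x.size == y.size):
        raise ValueError("subjects, x, y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    subj, x, y = subj[keep], x[keep], y[keep]
    uniq, idx = np.unique(subj, return_inverse=True)
    n_subjects = uniq.size
    n_pairs = x.size
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    counts = np.bincount(idx)
    if counts.min() < 2:
        raise ValueError("every subject needs at least 2 pairs")

    # within-subject centring removes the per-subject intercepts
    xc = x - np.bincount(idx, weights=x)[idx] / counts[idx]
    yc = y - np.bincount(idx, weights=y)[idx] / counts[idx]
    sxx = float(np.sum(xc * xc))
    if sxx == 0.0:
        raise ValueError("x is constant within every subject; slope undefined")
    slope = float(np.sum(xc * yc)) / sxx
    ss_x = float(np.sum(xc * yc)) ** 2 / sxx
    ss_err = float(np.sum((yc - slope * xc) ** 2))
    df = n_pairs - n_subjects - 1
    if df < 1:
        raise ValueError("not enough pairs for the degrees of freedom")
    denom = ss_x + ss_err
    r = 0.0 if denom == 0.0 else math.copysign(math.sqrt(ss_x / denom), slope)
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    if df > 1 and abs(r) < 1.0:
        z = math.atanh(r)
        half = stats.norm.ppf(0.975) / math.sqrt(df - 1)
        ci_low, ci_high = math.tanh(z - half), math.tanh(z + half)
    else:
        ci_low, ci_high = (-1.0, 1.0) if abs(r) < 1.0 else (r, r)
    return RmCorrResult(
        r_rm=r,
        df=int(df),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=p,
        n_pairs=int(n_pairs),
        n_subjects=int(n_subjects),
    )
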