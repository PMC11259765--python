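from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from ovutherm.diagnostics import (
    ContingencyTable,
    build_contingency,
    compute_metrics,
    mcnemar_from_counts,
    mcnemar_test,
    proportion_test,
    rmcorr,
)

CBT_TABLE = ContingencyTable(tp=51, fp=1, tn=13, fn=9)
BBT_TABLE = ContingencyTable(tp=41, fp=3, tn=11, fn=19)


class TestContingency:
    def test_build_from_calls_and_labels(self):
        calls = {"a": "biphasic", "b": "biphasic", "c": "monophasic", "d": "monophasic"}
        labels = {"a": "ovulatory", "b": "anovulatory", "c": "anovulatory", "d": "ovulatory"}
        ct = build_contingency(calls, labels)
        assert (ct.tp, ct.fp, ct.tn, ct.fn) == (1, 1, 1, 1)

    def test_mismatched_cycle_sets_rejected(self):
        with pytest.raises(ValueError):
            build_contingency({"a": "biphasic"}, {"b": "ovulatory"})
        with pytest.raises(ValueError):
            build_contingency({}, {})


class TestComputeMetrics:
    @pytest.mark.parametrize(
        "ct, sens, spec, ppv, npv, f1",
        [
            (CBT_TABLE, 85.00, 92.86, 98.08, 59.09, 0.91),
            (BBT_TABLE, 68.33, 78.57, 93.18, 36.67, 0.79),
        ],
    )
    def test_reference_tables(self, ct, sens, spec, ppv, npv, f1):
        r = compute_metrics(ct).rounded()
        assert r["sensitivity"] == sens
        assert r["specificity"] == spec
        assert r["ppv"] == ppv
        assert r["npv"] == npv
        assert r["f1"] == f1

    def test_perfect_classifier(self):
        r = compute_metrics(ContingencyTable(tp=10, fp=0, tn=10, fn=0)).rounded()
        assert all(r[m] == 100.0 for m in ("sensitivity", "specificity", "ppv", "npv"))
        assert r["f1"] == 1.0

    def test_zero_denominator_gives_undefined_metric(self):
        r = compute_metrics(ContingencyTable(tp=5, fp=0, tn=0, fn=0))
        assert r.specificity is None and r.npv is None
        assert r.sensitivity == 100.0

    def test_duality_under_class_swap(self):
        # swapping positives and negatives swaps sensitivity↔specificity
        a = compute_metrics(CBT_TABLE)
        b = compute_metrics(
            ContingencyTable(
                tp=CBT_TABLE.tn, fp=CBT_TABLE.fn, tn=CBT_TABLE.tp, fn=CBT_TABLE.fp
            )
        )
        assert a.sensitivity == pytest.approx(b.specificity)
        assert a.specificity == pytest.approx(b.sensitivity)

    def test_f1_is_harmonic_mean_of_ppv_and_sensitivity(self):
        r = compute_metrics(BBT_TABLE)
        p, s = r.ppv / 100, r.sensitivity / 100
        assert r.f1 == pytest.approx(2 * p * s / (p + s))


class TestMcNemar:
    def test_no_discordance(self):
        r = mcnemar_from_counts(0, 0)
        assert r.p_value == 1.0 and r.statistic == 0.0

    def test_exact_binomial_one_sided_discordance(self):
        r = mcnemar_from_counts(10, 0)
        assert r.method == "exact_binomial"
        assert r.p_value == pytest.approx(2 * 0.5**10, rel=1e-12)

    def test_continuity_corrected_chi2(self):
        r = mcnemar_from_counts(15, 5, method="chi2_cc")
        assert r.statistic == pytest.approx(4.05)
        auto = mcnemar_from_counts(20, 10)
        assert auto.method == "chi2_cc"
        assert auto.statistic == pytest.approx((abs(20 - 10) - 1) ** 2 / 30)

    @pytest.mark.parametrize("b, c", [(3, 8), (12, 20), (1, 0), (30, 11)])
    def test_matches_statsmodels(self, b, c):
        mine = mcnemar_from_counts(b, c)
        exact = b + c < 25
        ref = sm_mcnemar([[0, b], [c, 0]], exact=exact, correction=True)
        assert mine.p_value == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_symmetry_in_methods(self):
        ca = {"x": True, "y": False, "z": True, "w": False}
        cb = {"x": False, "y": True, "z": True, "w": False}
        r1 = mcnemar_test(ca, cb)
        r2 = mcnemar_test(cb, ca)
        assert (r1.b, r1.c) == (r2.c, r2.b)
        assert r1.p_value == pytest.approx(r2.p_value)


class TestProportionTest:
    def test_study_scale_proportions(self):
        r = proportion_test(52, 74, 44, 74)
        assert 0 < r.p_value < 1
        assert not r.degenerate

    def test_identical_proportions(self):
        r = proportion_test(30, 74, 30, 74)
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_maximal_difference(self):
        r = proportion_test(74, 74, 0, 74)
        assert r.p_value < 1e-15

    def test_degenerate_margins_flagged(self):
        r = proportion_test(10, 10, 8, 8)
        assert r.degenerate and math.isnan(r.p_value)


def _sim_repeated_measures(rng, n_subjects=20, n_per=10, rho=0.6, sd=1.0):
    subjects, xs, ys = [], [], []
    for s in range(n_subjects):
        mx, my = rng.normal(0, 3, size=2)
        x = mx + rng.normal(0, sd, size=n_per)
        y = my + rho * (x - mx) + math.sqrt(1 - rho**2) * rng.normal(0, sd, size=n_per)
        subjects += [f"s{s}"] * n_per
        xs += list(x)
        ys += list(y)
    return subjects, xs, ys


class TestRmCorr:
    def test_perfect_common_slope(self):
        subjects = ["a"] * 3 + ["b"] * 3
        x = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        y = [2 * v for v in x[:3]] + [2 * v + 5 for v in x[3:]]
        r = rmcorr(subjects, x, y)
        assert r.r_rm == pytest.approx(1.0)

    def test_null_relation_near_zero(self, rng):
        subjects, xs, ys = _sim_repeated_measures(rng, rho=0.0, n_subjects=40, n_per=20)
        r = rmcorr(subjects, xs, ys)
        assert abs(r.r_rm) < 0.1
        assert r.p_value > 0.01

    def test_df_accounting(self, rng):
        subjects, xs, ys = _sim_repeated_measures(rng, n_subjects=5, n_per=4)
        r = rmcorr(subjects, xs, ys)
        assert r.df == 20 - 5 - 1

    def test_matches_pingouin(self, rng):
        subjects, xs, ys = _sim_repeated_measures(rng)
        df = pd.DataFrame({"s": subjects, "x": xs, "y": ys})
        ref = pg.rm_corr(data=df, x="x", y="y", subject="s")
        mine = rmcorr(subjects, xs, ys)
        assert mine.r_rm == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert mine.df == int(ref["dof"].iloc[0])
        assert mine.p_value == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-6)
        lo, hi = ref["CI95"].iloc[0]
        assert mine.ci_low == pytest.approx(lo, abs=0.01)
        assert mine.ci_high == pytest.approx(hi, abs=0.01)

    def test_equals_centred_pearson_up_to_df(self, rng):
        subjects, xs, ys = _sim_repeated_measures(rng, n_subjects=6, n_per=8)
        subj = np.asarray(subjects)
        x, y = np.asarray(xs), np.asarray(ys)
        xc = np.concatenate([x[subj == s] - x[subj == s].mean() for s in np.unique(subj)])
        yc = np.concatenate([y[subj == s] - y[subj == s].mean() for s in np.unique(subj)])
        pearson = np.corrcoef(xc, yc)[0, 1]
        mine = rmcorr(subjects, xs, ys)
        assert mine.r_rm == pytest.approx(pearson, abs=1e-9)

    def test_invariant_to_per_subject_offsets(self, rng):
        subjects, xs, ys = _sim_repeated_measures(rng, n_subjects=8, n_per=6)
        base = rmcorr(subjects, xs, ys)
        offsets = {s: rng.normal(0, 10) for s in set(subjects)}
        ys2 = [y + offsets[s] for s, y in zip(subjects, ys)]
        shifted = rmcorr(subjects, xs, ys2)
        assert shifted.r_rm == pytest.approx(base.r_rm, abs=1e-9)

    def test_constant_within_subject_x_rejected(self):
        with pytest.raises(ValueError):
            rmcorr(["a", "a", "b", "b"], [1.0, 1.0, 2.0, 2.0], [1.0, 2.0, 3.0, 4.0])

    def test_parameter_recovery_coverage(self):
        # generating within-subject correlation 0.6 lies inside the 95% CI
        # in at least 90% of replicates
        hits = 0
        n_rep = 60
        for seed in range(n_rep):
            r = np.random.default_rng(1000 + seed)
            subjects, xs, ys = _sim_repeated_measures(r, n_subjects=20, n_per=10, rho=0.6)
            res = rmcorr(subjects, xs, ys)
            hits += res.ci_low <= 0.6 <= res.ci_high
        assert hits / n_rep >= 0.90
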