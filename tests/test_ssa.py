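"""Sequence ratios, Halls null-effect correction, exact CIs, classes."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from statsmodels.stats.proportion import proportion_confint

from reposignals import reference, ssa
from reposignals.studies import PUBLISHED_EXAMPLES, classify_published_example
from reposignals.types import SignalClass


def incident(d):
    return pd.DataFrame({"patient_id": list(d), "month": list(d.values())})


class TestBuildPairs:
    def test_diagnosis_after_within_window(self):
        pc = ssa.build_pairs(incident({"p": 3}), incident({"p": 5}), window=6)
        assert (pc.n_after, pc.n_before, pc.n_same_month) == (1, 0, 0)

    def test_gap_beyond_window_excluded(self):
        pc = ssa.build_pairs(incident({"p": 10}), incident({"p": 2}), window=6)
        assert pc.n == 0 and pc.n_same_month == 0

    def test_same_month_counted_but_excluded(self):
        pc = ssa.build_pairs(incident({"p": 4}), incident({"p": 4}), window=6)
        assert pc.n == 0 and pc.n_same_month == 1

    @given(st.dictionaries(st.integers(0, 9), st.tuples(
        st.integers(0, 23), st.integers(0, 23)), min_size=1, max_size=10),
        st.integers(1, 12))
    def test_matches_brute_force_enumeration(self, patients, window):
        drug = {f"p{k}": v[0] for k, v in patients.items()}
        dx = {f"p{k}": v[1] for k, v in patients.items()}
        pc = ssa.build_pairs(incident(drug), incident(dx), window)
        assert (pc.n_after, pc.n_before, pc.n_same_month) == \
            reference.brute_force_pairs(drug, dx, window)


class TestCrudeSr:
    @pytest.mark.parametrize("after,before,expected", [
        (3, 6, 0.5), (7, 7, 1.0)])
    def test_ratio(self, after, before, expected):
        pc = ssa.PairCounts(after, before, 0, 12)
        assert ssa.crude_sr(pc) == expected

    def test_zero_denominator_flagged_nan(self):
        assert math.isnan(ssa.crude_sr(ssa.PairCounts(6, 0, 0, 12)))


class TestNullEffectSr:
    def test_uniform_trends_give_one(self):
        d = np.full(24, 3)
        o = np.full(24, 5)
        for w in (1, 6, 12):
            assert ssa.null_effect_sr(d, o, w) == pytest.approx(1.0)

    def test_degenerate_denominator(self):
        # all outcome mass after all drug mass -> B = 0
        nsr = ssa.null_effect_sr(np.array([1, 0, 0]), np.array([0, 0, 1]), 2)
        assert math.isnan(nsr)
        a, b = ssa.null_effect_counts(np.array([1, 0, 0]),
                                      np.array([0, 0, 1]), 2)
        assert (a, b) == (1, 0)

    @given(st.integers(2, 12).flatmap(lambda m: st.tuples(
        st.lists(st.integers(0, 9), min_size=m, max_size=m),
        st.lists(st.integers(0, 9), min_size=m, max_size=m),
        st.integers(1, 4))))
    def test_equals_exhaustive_pair_enumeration_exactly(self, args):
        """Windowed null-effect SR equals brute-force enumeration over all
        independent (drug-month, diagnosis-month) pairs, in exact integer
        arithmetic."""
        d, o, w = args
        a, b = ssa.null_effect_counts(np.array(d), np.array(o), w)
        a_ref, b_ref = reference.brute_force_nsr(d, o, w)
        assert (a, b) == (a_ref, b_ref)
        if b:
            assert Fraction(a, b) == Fraction(a_ref, b_ref)


class TestClopperPearson:
    @given(st.integers(1, 200).flatmap(lambda n: st.tuples(
        st.just(n), st.integers(0, n))),
        st.sampled_from([0.01, 0.05, 0.1]))
    def test_matches_statsmodels_beta_interval(self, nk, alpha):
        n, k = nk
        lo, hi = ssa.clopper_pearson(k, n, alpha)
        sm_lo, sm_hi = proportion_confint(k, n, alpha=alpha, method="beta")
        assert lo == pytest.approx(0.0 if k == 0 else sm_lo, abs=1e-12)
        assert hi == pytest.approx(1.0 if k == n else sm_hi, abs=1e-12)

    def test_matches_binomial_tail_inversion(self):
        for k, n in [(0, 10), (5, 10), (20, 100), (99, 100)]:
            lo, hi = ssa.clopper_pearson(k, n)
            ref_lo, ref_hi = reference.clopper_pearson_by_inversion(k, n)
            assert lo == pytest.approx(ref_lo, abs=1e-9)
            assert hi == pytest.approx(ref_hi, abs=1e-9)


class TestAsrWithCi:
    def test_zero_numerator(self):
        res = ssa.asr_with_ci(ssa.PairCounts(0, 10, 0, 12), null_sr=1.0)
        assert res.asr == 0.0
        assert res.ci_low == 0.0
        assert res.ci_high > 0

    def test_balanced_counts_symmetric_on_odds_scale(self):
        res = ssa.asr_with_ci(ssa.PairCounts(5, 5, 0, 12), null_sr=1.0)
        assert res.asr == pytest.approx(1.0)
        assert res.ci_low == pytest.approx(1 / res.ci_high)

    def test_bounds_equal_beta_quantile_closed_form(self):
        """CI equals the Clopper-Pearson bounds mapped to odds and divided
        by the null-effect SR."""
        nsr = 1.1
        res = ssa.asr_with_ci(ssa.PairCounts(20, 80, 0, 12), null_sr=nsr)
        p_lo, p_hi = reference.clopper_pearson_by_inversion(20, 100)
        assert res.ci_low == pytest.approx(p_lo / (1 - p_lo) / nsr, rel=1e-9)
        assert res.ci_high == pytest.approx(p_hi / (1 - p_hi) / nsr, rel=1e-9)
        assert res.ci_low <= res.asr <= res.ci_high

    def test_asr_times_nsr_equals_crude(self):
        pc = ssa.PairCounts(13, 29, 2, 24)
        res = ssa.asr_with_ci(pc, null_sr=0.85)
        assert res.asr * res.null_sr == pytest.approx(ssa.crude_sr(pc))

    def test_all_after_gives_infinite_upper_bound(self):
        res = ssa.asr_with_ci(ssa.PairCounts(10, 0, 0, 12), null_sr=1.0)
        assert math.isinf(res.asr) and math.isinf(res.ci_high)

    def test_empty_pairs_flagged(self):
        res = ssa.asr_with_ci(ssa.PairCounts(0, 0, 3, 12), null_sr=1.0)
        assert not res.defined

    def test_alpha_monotonicity(self):
        """Widening alpha narrows the interval; more data (same proportion)
        never widens it."""
        pc = ssa.PairCounts(20, 80, 0, 12)
        narrow = ssa.asr_with_ci(pc, 1.0, alpha=0.10)
        wide = ssa.asr_with_ci(pc, 1.0, alpha=0.01)
        assert wide.ci_low < narrow.ci_low < narrow.ci_high < wide.ci_high
        big = ssa.asr_with_ci(ssa.PairCounts(200, 800, 0, 12), 1.0)
        small = ssa.asr_with_ci(pc, 1.0)
        assert (big.ci_high - big.ci_low) <= (small.ci_high - small.ci_low)

    def test_nominal_coverage_at_hundred_pairs(self):
        """95% intervals cover the true ratio in >= 93% of 200 replicates."""
        rng = np.random.default_rng(7)
        true_ratio = 0.5
        p = true_ratio / (1 + true_ratio)
        n = 100
        hits = 0
        for _ in range(200):
            k = rng.binomial(n, p)
            res = ssa.asr_with_ci(ssa.PairCounts(k, n - k, 0, 12),
                                  null_sr=1.0)
            hits += res.ci_low <= true_ratio <= res.ci_high
        assert hits / 200 >= 0.93


class TestClassifySsa:
    def _results(self, bounds):
        return [ssa.SsaResult(drug="d", disease="s", window=w, n_after=0,
                              n_before=0, n_same_month=0, crude_sr=e,
                              null_sr=1.0, asr=e, ci_low=lo, ci_high=hi)
                for w, e, lo, hi in bounds]

    def test_inverse_requires_three_of_four_windows(self):
        halo = PUBLISHED_EXAMPLES["haloperidol"]
        s, _ = classify_published_example(halo, "CD")
        assert s is SignalClass.INVERSE
        # UC: window 6 interval crosses 1, still 3 of 4 significant
        s, _ = classify_published_example(halo, "UC")
        assert s is SignalClass.INVERSE

    def test_two_significant_windows_is_none(self):
        res = self._results([(6, 0.5, 0.3, 0.9), (12, 0.5, 0.3, 0.9),
                             (24, 0.8, 0.5, 1.2), (36, 0.8, 0.5, 1.2)])
        assert ssa.classify_ssa(res) is SignalClass.NONE

    def test_all_lower_bounds_above_one_is_risk(self):
        res = self._results([(w, 2.0, 1.3, 3.1) for w in (6, 12, 24, 36)])
        assert ssa.classify_ssa(res) is SignalClass.RISK

    def test_undefined_windows_not_significant(self):
        res = self._results([(6, 0.5, 0.3, 0.9), (12, 0.5, 0.3, 0.9)])
        res.append(ssa.SsaResult(
            drug="d", disease="s", window=24, n_after=0, n_before=0,
            n_same_month=0, crude_sr=float("nan"), null_sr=float("nan"),
            asr=float("nan"), ci_low=float("nan"), ci_high=float("nan")))
        assert ssa.classify_ssa(res) is SignalClass.NONE


class TestRunSsa:
    def test_sweep_shapes_and_identity(self):
        """The orchestrated sweep reproduces the per-operation composition."""
        rng = np.random.default_rng(3)
        n = 400
        events = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(n)] * 2,
            "month": np.concatenate([rng.integers(0, 48, n),
                                     rng.integers(0, 48, n)]),
            "kind": ["prescription"] * n + ["diagnosis"] * n,
            "code": ["D1"] * n + ["C1"] * n,
        })
        enrollment = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(n)],
            "enroll_month": 0, "disenroll_month": 48})
        table, classes = ssa.run_ssa(events, enrollment, ["D1"], ["C1"],
                                     study_months=48, windows=(6, 12))
        assert len(table) == 2
        assert set(classes) == {("D1", "C1")}
        for row in table.itertuples():
            if math.isfinite(row.asr):
                assert row.asr * row.null_sr == pytest.approx(row.crude_sr)
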