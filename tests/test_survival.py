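import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from lifelines.statistics import logrank_test

from emtdubscreen import (
    CutpointError,
    EmtScreenError,
    SyntheticConfig,
    UndefinedTestError,
    generate_cohort,
    generate_survival,
    km_estimate,
    logrank,
    optimal_cutpoint,
)

from conftest import make_clinical
from oracles import km_brute, logrank_brute


class TestKMEstimate:
    def test_three_uncensored_events(self):
        curve = km_estimate(make_clinical([1, 2, 3], [1, 1, 1]))
        assert curve.times.tolist() == [1.0, 2.0, 3.0]
        assert curve.survival == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert curve.at_risk.tolist() == [3, 2, 1]

    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate(make_clinical([5, 6, 7], [0, 0, 0]))
        assert curve.times.size == 0
        assert curve.survival_at([0.0, 5.5, 100.0]) == pytest.approx([1, 1, 1])

    def test_hand_worked_mixed_censoring(self, clinical_four):
        # events at 1 and 3, censored at 2 and 4: risk set 4 -> 2 after t=2
        curve = km_estimate(clinical_four)
        assert curve.survival_at(1.0)[0] == pytest.approx(3 / 4)
        assert curve.survival_at(3.0)[0] == pytest.approx(3 / 8)

    def test_empty_input_is_error(self):
        with pytest.raises(EmtScreenError):
            km_estimate(make_clinical([], []))

    @given(st.lists(st.tuples(st.floats(0.1, 50), st.integers(0, 1)),
                    min_size=1, max_size=15))
    def test_curve_non_increasing_within_unit_interval(self, subjects):
        times, events = zip(*subjects)
        curve = km_estimate(make_clinical(times, events))
        assert np.all(curve.survival >= -1e-12)
        assert np.all(curve.survival <= 1 + 1e-12)
        assert np.all(np.diff(curve.survival) <= 1e-12)

    @given(st.lists(st.tuples(st.integers(1, 6), st.integers(0, 1)),
                    min_size=1, max_size=8))
    def test_agrees_with_brute_force_product_limit(self, subjects):
        times, events = zip(*subjects)
        curve = km_estimate(make_clinical(times, events))
        t_o, s_o, r_o = km_brute(times, events)
        assert curve.times.tolist() == t_o
        assert curve.survival == pytest.approx(s_o, abs=1e-9)
        assert curve.at_risk.tolist() == r_o


class TestLogrank:
    def test_identical_groups_yield_null_statistic(self):
        a = make_clinical([1, 2, 3], [1, 1, 0], prefix="a")
        b = make_clinical([1, 2, 3], [1, 1, 0], prefix="b")
        chi, p = logrank(a, b)
        assert chi == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_worked_example(self):
        # O_a = 2, E_a = 1/2 + 1/3 = 0.8333, V = 1/4 + 2/9 = 0.4722
        a = make_clinical([1, 2], [1, 1], prefix="a")
        b = make_clinical([3, 4], [1, 1], prefix="b")
        chi, p = logrank(a, b)
        assert chi == pytest.approx((2 - 5 / 6) ** 2 / (1 / 4 + 2 / 9), abs=1e-9)
        assert chi == pytest.approx(2.88, abs=0.01)

    def test_group_label_symmetry(self):
        a = make_clinical([1, 4, 6, 8], [1, 0, 1, 1], prefix="a")
        b = make_clinical([2, 3, 9], [1, 1, 0], prefix="b")
        assert logrank(a, b) == pytest.approx(logrank(b, a))

    def test_zero_events_undefined(self):
        a = make_clinical([1, 2], [0, 0], prefix="a")
        b = make_clinical([3], [0], prefix="b")
        with pytest.raises(UndefinedTestError):
            logrank(a, b)

    def test_empty_group_rejected(self):
        with pytest.raises(EmtScreenError):
            logrank(make_clinical([], []), make_clinical([1], [1]))

    def test_exhaustive_small_patterns_match_brute_force_and_lifelines(self):
        # every event/censor pattern over 2+2 and 3+2 subjects on a tied grid
        times_grid = [1, 2, 2, 3, 4]
        for n_a in (2, 3):
            for events in itertools.product([0, 1], repeat=5):
                if sum(events) == 0:
                    continue
                t_a, e_a = times_grid[:n_a], events[:n_a]
                t_b, e_b = times_grid[n_a:], events[n_a:]
                chi, p = logrank(make_clinical(t_a, e_a, "a"),
                                 make_clinical(t_b, e_b, "b"))
                chi_o, p_o = logrank_brute(t_a, e_a, t_b, e_b)
                assert chi == pytest.approx(chi_o, abs=1e-9)
                assert p == pytest.approx(p_o, abs=1e-9)
                res = logrank_test(t_a, t_b, event_observed_A=e_a,
                                   event_observed_B=e_b)
                if chi_o > 0:
                    assert chi == pytest.approx(res.test_statistic, abs=1e-6)

    @given(st.lists(st.tuples(st.integers(1, 8), st.integers(0, 1)),
                    min_size=2, max_size=8),
           st.integers(1, 7))
    def test_random_tables_match_brute_force(self, subjects, split):
        split = min(split, len(subjects) - 1)
        times, events = zip(*subjects)
        if sum(events) == 0:
            return
        t_a, e_a = times[:split], events[:split]
        t_b, e_b = times[split:], events[split:]
        chi, p = logrank(make_clinical(t_a, e_a, "a"),
                         make_clinical(t_b, e_b, "b"))
        chi_o, p_o = logrank_brute(t_a, e_a, t_b, e_b)
        assert chi == pytest.approx(chi_o, abs=1e-9)
        assert p == pytest.approx(p_o, abs=1e-9)


def _survival_fixture(seed=0, n=200):
    cfg = SyntheticConfig(seed=seed, n_samples=n, n_signature=0, n_null_family=0)
    cohort = generate_cohort(cfg)
    clinical = generate_survival(cohort, cfg)
    return cohort, clinical


class TestOptimalCutpoint:
    def test_constant_expression_is_error(self):
        _, clinical = _survival_fixture()
        expr = pd.Series(1.0, index=clinical.sample_ids)
        with pytest.raises(CutpointError):
            optimal_cutpoint(expr, clinical)

    def test_threshold_within_quantile_window(self):
        cohort, clinical = _survival_fixture(seed=4)
        expr = cohort.expression.gene("STAMBPL1")
        result = optimal_cutpoint(expr, clinical)
        lo, hi = np.quantile(expr.to_numpy(), [0.25, 0.75])
        assert lo < result.threshold < hi
        assert result.n_low + result.n_high == len(expr)
        assert result.n_thresholds_scanned >= 1

    def test_minimal_p_not_worse_than_median_split(self):
        from emtdubscreen.survival import _logrank_arrays
        cohort, clinical = _survival_fixture(seed=5)
        expr = cohort.expression.gene("STAMBPL1")
        result = optimal_cutpoint(expr, clinical)
        values = expr.to_numpy()
        med = float(np.median(values))
        _, p_median = _logrank_arrays(clinical.time, clinical.event, values <= med)
        assert result.p <= p_median + 1e-12

    def test_tie_break_prefers_smallest_threshold(self):
        # flat survival signal: many thresholds tie at p=1-ish; determinism
        clinical = make_clinical([1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 1])
        expr = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                         index=clinical.sample_ids)
        r1 = optimal_cutpoint(expr, clinical)
        r2 = optimal_cutpoint(expr, clinical)
        assert r1.threshold == r2.threshold

    def test_recovers_planted_median_dichotomy(self):
        cohort, clinical = _survival_fixture(seed=6, n=300)
        expr = cohort.expression.gene("STAMBPL1")
        result = optimal_cutpoint(expr, clinical)
        lo, hi = np.quantile(expr.to_numpy(), [0.4, 0.6])
        assert lo <= result.threshold <= hi
        assert result.p < 0.01

    def test_scan_size_exposed_for_selection_effect(self):
        cohort, clinical = _survival_fixture(seed=8)
        expr = cohort.expression.gene("STAMBPL1")
        result = optimal_cutpoint(expr, clinical, q_low=0.4, q_high=0.6)
        narrow = result.n_thresholds_scanned
        wide = optimal_cutpoint(expr, clinical).n_thresholds_scanned
        assert narrow < wide
        assert "not corrected" in result.caveat

    def test_min_expression_prefilter(self):
        cohort, clinical = _survival_fixture(seed=9)
        expr = cohort.expression.gene("STAMBPL1")
        cut = float(np.quantile(expr, 0.1))
        result = optimal_cutpoint(expr, clinical, min_expression=cut)
        assert result.n_low + result.n_high == int((expr > cut).sum())
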