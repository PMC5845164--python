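"""Risk tables, weighted Kaplan-Meier, and weighted cumulative incidence."""

import numpy as np
import pytest

from ipwrmst import (
    EventCoding,
    build_risk_table,
    composite_cif,
    weighted_cif,
    weighted_km,
    weighted_overall_survival,
)

from conftest import brute_cif, brute_km, make_cohort, random_cohort


class TestBuildRiskTable:
    def test_horizon_beyond_follow_up_errors(self, four_subject_cohort, coding):
        with pytest.raises(ValueError, match="exceeds maximum observed follow-up"):
            build_risk_table(four_subject_cohort, None, coding, 5.0)

    def test_unit_weight_hand_count(self, four_subject_cohort, coding):
        rt = build_risk_table(four_subject_cohort, None, coding, 4.0)
        assert np.array_equal(rt.times, [1.0, 2.0, 4.0])
        assert np.array_equal(rt.n_w, [4.0, 3.0, 1.0])
        assert np.array_equal(rt.d_w_by_type[1], [1.0, 1.0, 0.0])

    def test_weighted_hand_count(self, four_subject_cohort, coding):
        rt = build_risk_table(four_subject_cohort, np.array([2.0, 1.0, 1.0, 1.0]), coding, 4.0)
        assert np.array_equal(rt.n_w, [5.0, 3.0, 1.0])
        assert np.array_equal(rt.d_w_by_type[1], [2.0, 1.0, 0.0])

    def test_at_risk_total_non_increasing_and_events_bounded(self):
        rng = np.random.default_rng(0)
        coding = EventCoding(1, frozenset({2}))
        for _ in range(50):
            cohort, w = random_cohort(rng)
            rt = build_risk_table(cohort, w, coding, float(cohort.time.max()))
            assert np.all(np.diff(rt.n_w) <= 1e-12)
            assert np.all(rt.d_w <= rt.n_w + 1e-12)

    def test_ties_remove_events_before_censorings(self, coding):
        # event and censoring both at t=2: the censored subject is still at risk
        cohort = make_cohort([2, 2, 3], [1, 0, 0], exposure=[0, 1, 0])
        rt = build_risk_table(cohort, None, coding, 3.0)
        assert rt.n_w[0] == 3.0 and rt.d_w_by_type[1][0] == 1.0

    def test_unknown_event_code_rejected(self, coding):
        cohort = make_cohort([1, 2], [1, 7])
        with pytest.raises(ValueError, match=r"\[7\]"):
            build_risk_table(cohort, None, coding, 2.0)


class TestWeightedKM:
    def test_all_censored_survival_is_one(self, coding):
        cohort = make_cohort([1, 2, 3, 4], [0, 0, 0, 0])
        curve = weighted_km(build_risk_table(cohort, None, coding, 4.0))
        assert np.array_equal(curve.values, np.ones(curve.values.size))

    def test_hand_product_limit(self, four_subject_cohort, coding):
        curve = weighted_km(build_risk_table(four_subject_cohort, None, coding, 4.0))
        assert curve(0.0) == 1.0
        assert curve(1.0) == 0.75
        assert curve(2.0) == 0.5

    def test_weight_scale_invariance(self, four_subject_cohort, coding):
        w = np.array([0.7, 1.3, 2.1, 0.4])
        km1 = weighted_km(build_risk_table(four_subject_cohort, w, coding, 4.0))
        km2 = weighted_km(build_risk_table(four_subject_cohort, 17.0 * w, coding, 4.0))
        assert np.allclose(km1.values, km2.values, rtol=0, atol=1e-15)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        coding = EventCoding(1)
        for _ in range(100):
            cohort, w = random_cohort(rng, n_types=1)
            horizon = float(cohort.time.max())
            curve = weighted_km(build_risk_table(cohort, w, coding, horizon))
            grid = np.unique(cohort.time)
            grid = grid[grid <= horizon]
            expected = brute_km(cohort.time, cohort.event_type, w, grid)
            assert np.allclose(curve(grid), expected, rtol=0, atol=1e-12)


class TestOverallSurvivalModes:
    def test_exp_cumhaz_evaluates_printed_form(self, four_subject_cohort, coding):
        rt = build_risk_table(four_subject_cohort, None, coding, 4.0)
        curve = weighted_overall_survival(rt, mode="exp_cumhaz")
        assert curve(1.0) == pytest.approx(np.exp(-0.25), abs=1e-15)
        assert curve(2.0) == pytest.approx(np.exp(-0.25 - 1 / 3), abs=1e-15)

    def test_no_events_both_modes_identity(self, coding):
        cohort = make_cohort([1, 2, 3], [0, 0, 0], exposure=[0, 1, 0])
        rt = build_risk_table(cohort, None, coding, 3.0)
        for mode in ("product_limit", "exp_cumhaz"):
            assert np.all(weighted_overall_survival(rt, mode).values == 1.0)

    def test_exp_form_dominates_product_limit(self, four_subject_cohort, coding):
        # 1 - h <= exp(-h): the exponential form always sits above
        rt = build_risk_table(four_subject_cohort, None, coding, 4.0)
        pl = weighted_overall_survival(rt, "product_limit").values
        ex = weighted_overall_survival(rt, "exp_cumhaz").values
        assert np.all(ex >= pl)
        assert ex[1] > pl[1]


class TestWeightedCIF:
    def test_hand_aalen_johansen(self, competing_cohort, competing_coding):
        rt = build_risk_table(competing_cohort, None, competing_coding, 4.0)
        f1 = weighted_cif(rt, 1)
        f2 = weighted_cif(rt, 2)
        s = weighted_km(rt)
        assert f1(4.0) == pytest.approx(0.25, abs=1e-15)
        assert f2(4.0) == pytest.approx(0.75 * (1 / 3), abs=1e-15)
        assert f1(4.0) + f2(4.0) + s(4.0) == pytest.approx(1.0, abs=1e-15)

    def test_cif_starts_at_zero_and_is_monotone(self, competing_cohort, competing_coding):
        rt = build_risk_table(competing_cohort, None, competing_coding, 4.0)
        f1 = weighted_cif(rt, 1)
        assert f1(0.0) == 0.0
        assert np.all(np.diff(f1.values) >= 0)

    def test_single_event_type_complement_identity(self, four_subject_cohort, coding):
        rt = build_risk_table(four_subject_cohort, None, coding, 4.0)
        f1 = weighted_cif(rt, 1)
        s = weighted_km(rt)
        assert np.allclose(f1.values, 1.0 - s.values, rtol=0, atol=1e-15)

    def test_unknown_event_type_rejected(self, four_subject_cohort, coding):
        rt = build_risk_table(four_subject_cohort, None, coding, 4.0)
        with pytest.raises(KeyError):
            weighted_cif(rt, 9)

    def test_additivity_at_every_knot_product_limit(self):
        rng = np.random.default_rng(7)
        coding = EventCoding(1, frozenset({2, 3}))
        for _ in range(100):
            cohort, w = random_cohort(rng, n_types=3)
            rt = build_risk_table(cohort, w, coding, float(cohort.time.max()))
            total = weighted_km(rt).values.copy()
            for code in (1, 2, 3):
                total += weighted_cif(rt, code).values
            assert np.allclose(total, 1.0, rtol=0, atol=1e-12)

    def test_exp_cumhaz_mode_overshoots_one(self):
        rng = np.random.default_rng(8)
        coding = EventCoding(1, frozenset({2}))
        cohort, w = random_cohort(rng, n_types=2)
        rt = build_risk_table(cohort, w, coding, float(cohort.time.max()))
        total = weighted_overall_survival(rt, "exp_cumhaz").values.copy()
        for code in (1, 2):
            total += weighted_cif(rt, code, mode="exp_cumhaz").values
        assert np.all(total >= 1.0 - 1e-12)
        if rt.d_w.sum() > 0:
            assert total[-1] > 1.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(43)
        coding = EventCoding(1, frozenset({2}))
        for _ in range(100):
            cohort, w = random_cohort(rng, n_types=2)
            horizon = float(cohort.time.max())
            rt = build_risk_table(cohort, w, coding, horizon)
            grid = np.unique(cohort.time)
            for code in (1, 2):
                curve = weighted_cif(rt, code)
                expected = brute_cif(cohort.time, cohort.event_type, w, code, grid)
                assert np.allclose(curve(grid), expected, rtol=0, atol=1e-12)

    def test_bounded_by_competing_complement(self):
        rng = np.random.default_rng(9)
        coding = EventCoding(1, frozenset({2}))
        for _ in range(30):
            cohort, w = random_cohort(rng, n_types=2)
            rt = build_risk_table(cohort, w, coding, float(cohort.time.max()))
            f1 = weighted_cif(rt, 1).values
            f2 = weighted_cif(rt, 2).values
            assert np.all(f1 <= 1.0 - f2 + 1e-12)

    def test_composite_cif_is_sum_of_parts(self, competing_cohort, competing_coding):
        rt = build_risk_table(competing_cohort, None, competing_coding, 4.0)
        comp = composite_cif(rt, [2])
        assert np.allclose(comp.values, weighted_cif(rt, 2).values, atol=1e-15)


def test_late_censored_subject_never_raises_hazards(coding):
    """Adding a subject censored after all events only grows risk sets."""
    base = make_cohort([1, 2, 3], [1, 1, 0], exposure=[0, 1, 0])
    extra = make_cohort([1, 2, 3, 9], [1, 1, 0, 0], exposure=[0, 1, 0, 1])
    rt_a = build_risk_table(base, None, coding, 3.0)
    rt_b = build_risk_table(extra, None, coding, 3.0)
    assert np.all(rt_b.hazard(None) <= rt_a.hazard(None) + 1e-15)


def test_lifelines_cross_check_unweighted_km(four_subject_cohort, coding):
    lifelines = pytest.importorskip("lifelines")
    rt = build_risk_table(four_subject_cohort, None, coding, 4.0)
    ours = weighted_km(rt)
    kmf = lifelines.KaplanMeierFitter().fit(
        four_subject_cohort.time, four_subject_cohort.event_type != 0
    )
    grid = [0.5, 1.0, 2.0, 3.5]
    theirs = kmf.survival_function_at_times(grid).to_numpy()
    assert np.allclose(ours(grid), theirs, atol=1e-12)
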