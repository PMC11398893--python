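"""Weighted-mean aggregation, dose intensity, cycle and cohort summaries."""

from __future__ import annotations

import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mtaudit.intensity import (
    WeightedSeries,
    anc_band_percentages,
    combined_intensity,
    compare_cohorts,
    dose_intensity,
    interval_weights,
    round_half_up,
    summarize_cohort,
    summarize_course,
    summarize_cycles,
    time_in_target,
    weighted_mean,
)
from mtaudit.model import ProtocolRules
from mtaudit.synthetic import PrescriberModel, simulate_cohort

from conftest import build_course


class TestIntervalWeights:
    @pytest.mark.parametrize(
        "weeks,end,expected",
        [
            ([0, 1, 2, 3], 4, [1, 1, 1, 1]),
            ([0, 2, 6], 7, [2, 4, 1]),
            ([0], 96, [96]),
            ([0, 5], 5, [5, 1]),  # last-visit weight floored at one week
        ],
    )
    def test_examples(self, weeks, end, expected):
        assert interval_weights(weeks, end) == expected

    def test_empty_series_errors(self):
        with pytest.raises(ValueError):
            interval_weights([], 96)

    def test_non_increasing_errors(self):
        with pytest.raises(ValueError):
            interval_weights([0, 2, 2], 96)


class TestWeightedMean:
    def test_hand_example(self):
        s = WeightedSeries([0, 2, 6], [1.0, 2.0, 1.0], [2, 4, 1])
        assert weighted_mean(s) == pytest.approx(11 / 7)

    def test_constant_series(self):
        assert weighted_mean(WeightedSeries([0, 1, 2], [1, 1, 1], [3, 1, 9])) == 1

    def test_symmetry(self):
        assert weighted_mean(WeightedSeries([0, 1], [0, 2], [1, 1])) == 1

    def test_missing_values_dropped_with_weights(self):
        s = WeightedSeries([0, 1, 2], [1.0, None, 3.0], [1, 100, 1])
        assert weighted_mean(s) == pytest.approx(2.0)

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            weighted_mean(WeightedSeries([0, 1], [None, None], [1, 1]))

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=20))
    def test_uniform_weights_equal_arithmetic_mean(self, values):
        s = WeightedSeries(range(len(values)), values, [1.0] * len(values))
        assert weighted_mean(s) == pytest.approx(np.mean(values), abs=1e-12, rel=1e-12)

    @given(
        st.lists(
            st.tuples(st.floats(-1e3, 1e3), st.floats(0.01, 10.0)),
            min_size=1, max_size=20,
        )
    )
    def test_bounded_by_min_and_max(self, pairs):
        values = [v for v, _ in pairs]
        weights = [w for _, w in pairs]
        m = weighted_mean(WeightedSeries(range(len(values)), values, weights))
        assert min(values) - 1e-9 <= m <= max(values) + 1e-9


class TestDoseIntensity:
    def test_protocol_dose_is_100(self):
        assert dose_intensity(420.0, 60.0, 1.0, "MP") == pytest.approx(100.0)
        assert dose_intensity(20.0, 20.0, 1.0, "MTX") == pytest.approx(100.0)

    def test_mp_hand_example(self):
        # daily 60 mg/m2 at BSA 0.8 -> 336 mg/week protocol; 168 -> 50%
        assert dose_intensity(168.0, 60.0, 0.8, "MP") == pytest.approx(50.0)

    def test_stop_is_zero(self):
        assert dose_intensity(0.0, 60.0, 0.8, "MP") == 0.0

    def test_negative_dose_errors(self):
        with pytest.raises(ValueError):
            dose_intensity(-1.0, 60.0, 0.8, "MP")

    @given(st.floats(0.1, 1000), st.floats(1, 100), st.floats(0.3, 2.5),
           st.floats(1.1, 10))
    def test_homogeneous_in_dose_and_protocol(self, dose, proto, bsa, c):
        di = dose_intensity(dose, proto, bsa, "MTX")
        assert dose_intensity(c * dose, c * proto, bsa, "MTX") == pytest.approx(di)


class TestCombinedIntensity:
    @pytest.mark.parametrize("mp,mtx,expected", [
        (100, 100, 100),
        (150, 160, 240),  # tolerable-intensity scale for an up-titrated course
        (0, 73, 0),
    ])
    def test_examples(self, mp, mtx, expected):
        assert combined_intensity(mp, mtx) == pytest.approx(expected)

    @given(st.floats(0, 300), st.floats(0, 300), st.floats(0, 50))
    def test_monotone_in_each_argument(self, a, b, delta):
        assert combined_intensity(a + delta, b) >= combined_intensity(a, b) - 1e-9
        assert combined_intensity(a, b + delta) >= combined_intensity(a, b) - 1e-9


def _step_mean_oracle(weeks, values, end_week, grid=0.25):
    """Rectangle integration of the forward-carry step function."""
    ts = np.arange(weeks[0], end_week, grid)
    vals = np.empty_like(ts)
    for i, t in enumerate(ts):
        j = np.searchsorted(weeks, t, side="right") - 1
        vals[i] = values[j]
    return float(vals.mean())


def test_weighted_mean_matches_step_integration_oracle():
    """Interval weights reproduce exact time-averaging of the step function."""
    rng = np.random.default_rng(20250901)
    for _ in range(50):
        n = rng.integers(1, 11)
        weeks = np.sort(rng.choice(np.arange(0, 90), size=n, replace=False)).astype(float)
        values = rng.uniform(0, 5, size=n)
        end = float(weeks[-1] + rng.integers(1, 10))
        wm = weighted_mean(WeightedSeries(weeks, list(values), interval_weights(weeks, end)))
        assert wm == pytest.approx(_step_mean_oracle(weeks, values, end), rel=1e-10)


class TestCycles:
    def test_uniform_protocol_course(self, rules, protocol_course):
        cycles = summarize_cycles(protocol_course, rules)
        assert len(cycles) == 8
        for c in cycles:
            assert c.wm_anc == pytest.approx(1.0)
            assert c.wm_di_combined == pytest.approx(100.0)
            assert c.n_visits == 12
            assert c.total_weight == pytest.approx(12.0)

    def test_anc_doubled_in_cycle_2_only(self, rules):
        anc = [2.0 if 12 <= w < 24 else 1.0 for w in range(96)]
        course = build_course(list(range(96)), anc=anc)
        cycles = summarize_cycles(course, rules)
        for c in cycles:
            assert c.wm_anc == pytest.approx(2.0 if c.cycle_index == 2 else 1.0)

    def test_boundary_spanning_interval_split(self, rules):
        # visit at week 10 carries to week 14: 2 weeks in cycle 1, 2 in cycle 2
        course = build_course([0, 10, 14], anc=[1.0, 3.0, 1.0], mt_end_week=96)
        cycles = summarize_cycles(course, rules)
        c1, c2 = cycles[0], cycles[1]
        assert c1.total_weight == pytest.approx(12.0)
        assert c1.wm_anc == pytest.approx((10 * 1.0 + 2 * 3.0) / 12)
        assert c2.wm_anc == pytest.approx((2 * 3.0 + 10 * 1.0) / 12)

    def test_mass_conservation(self, rules):
        """Weight-weighted cycle means reproduce the whole-course mean."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = rng.integers(2, 40)
            weeks = np.sort(rng.choice(np.arange(0, 96), size=n, replace=False))
            course = build_course(
                list(map(float, weeks)),
                anc=list(rng.uniform(0.2, 3.0, size=n)),
                mp=list(rng.choice([0, 105, 210, 420], size=n).astype(float)),
            )
            cycles = summarize_cycles(course, rules)
            overall = summarize_course(course, rules)
            tw = sum(c.total_weight for c in cycles)
            anc_recomb = sum(c.wm_anc * c.total_weight for c in cycles) / tw
            mp_recomb = sum(c.wm_di_mp * c.total_weight for c in cycles) / tw
            assert anc_recomb == pytest.approx(overall.wm_anc, abs=1e-9)
            assert mp_recomb == pytest.approx(overall.wm_di_mp, abs=1e-9)


class TestCourseSummary:
    def test_constant_protocol_course(self, rules, protocol_course):
        s = summarize_course(protocol_course, rules)
        assert s.wm_di_combined == pytest.approx(100.0)
        assert s.in_anc_target and s.above_di_threshold
        assert s.time_in_target_pct == pytest.approx(100.0)

    def test_piecewise_half_dose(self, rules):
        mp = [420.0] * 48 + [210.0] * 48
        course = build_course(list(range(96)), mp=mp)
        s = summarize_course(course, rules)
        assert s.wm_di_mp == pytest.approx(75.0)
        assert s.wm_di_combined == pytest.approx(75.0)


class TestTimeInTarget:
    def test_all_in_range(self, rules, protocol_course):
        assert time_in_target(protocol_course, rules) == pytest.approx(100.0)

    def test_ten_weeks_of_96_rounds_to_10(self, rules):
        anc = [1.0 if w < 10 else 2.0 for w in range(96)]
        course = build_course(list(range(96)), anc=anc)
        assert round_half_up(time_in_target(course, rules)) == 10

    def test_alternating_equal_weights(self, rules):
        anc = [1.0 if w % 2 == 0 else 2.0 for w in range(96)]
        course = build_course(list(range(96)), anc=anc)
        assert time_in_target(course, rules) == pytest.approx(50.0)

    def test_no_anc_errors(self, rules):
        course = build_course([0, 1], anc=[None, None], plt=[100, 100])
        with pytest.raises(ValueError):
            time_in_target(course, rules)

    def test_final_three_cycles_above_range(self, rules):
        """36 of 96 weeks above target rounds to 38% of the course."""
        anc = [2.0 if w >= 60 else 1.0 for w in range(96)]
        course = build_course(list(range(96)), anc=anc)
        bands = anc_band_percentages(course, rules)
        assert bands["above"] == pytest.approx(100 * 36 / 96)
        assert round_half_up(bands["above"]) == 38


class TestCohort:
    def _mixed_cohort(self):
        # 10 protocol-dose patients (DI 100) and 10 at 40% flat
        full = [build_course(list(range(96)), patient_id=f"F{i}") for i in range(10)]
        low = [build_course(list(range(96)), mp=[168.0] * 96, mtx=[8.0] * 96,
                            patient_id=f"L{i}") for i in range(10)]
        return full + low

    def test_counts_at_threshold(self, rules):
        cs = summarize_cohort(self._mixed_cohort(), rules)
        assert cs.n_above_di_threshold == 10
        assert cs.n_above_di_in_anc_target == 10  # ANC 1.0 everywhere

    def test_single_patient_counts(self, rules):
        cs = summarize_cohort([build_course(list(range(96)))], rules)
        assert cs.n_above_di_threshold in (0, 1)

    def test_disjoint_groups_rank_sum_significant(self, rules):
        courses = self._mixed_cohort()
        groups = {c.patient_id: ("a" if c.patient_id.startswith("F") else "b")
                  for c in courses}
        rep = compare_cohorts(courses, rules, groups=groups)
        assert rep.tests["wm_di_combined"][1] < 0.01

    def test_identical_groups_statistic_at_null_center(self, rules):
        # same patients duplicated under two labels -> U at n1*n2/2
        courses = []
        groups = {}
        for g in ("a", "b"):
            for i in range(6):
                pid = f"{g}{i}"
                courses.append(build_course(list(range(96)), anc=[1.0 + 0.1 * i] * 96,
                                            patient_id=pid))
                groups[pid] = g
        rep = compare_cohorts(courses, rules, groups=groups)
        assert rep.tests["wm_anc"][0] == pytest.approx(6 * 6 / 2)

    def test_split_by_intervention_date(self, rules):
        courses = []
        for i in range(6):
            c = build_course(list(range(96)), patient_id=f"P{i}")
            c.mt_start = dt.date(2018, 1, 1) if i < 3 else dt.date(2020, 1, 1)
            courses.append(c)
        rep = compare_cohorts(courses, rules,
                              intervention_date=dt.date(2019, 5, 15))
        assert tuple(len(g) for g in rep.groups) == (3, 3)

    def test_null_simulation_p_values_rarely_significant(self, rules):
        """Two arms from the same generator: rank-sum p > 0.05 in >=90/100."""
        ok = 0
        for seed in range(100):
            courses, _ = simulate_cohort(
                12, {"standard": 1.0}, PrescriberModel(), rules, seed=seed
            )
            groups = {c.patient_id: ("a" if i < 6 else "b")
                      for i, c in enumerate(courses)}
            rep = compare_cohorts(courses, rules, groups=groups)
            if rep.tests["wm_di_combined"][1] > 0.05:
                ok += 1
        assert ok >= 90
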