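"""Interval-weighted dose-intensity and blood-count summaries.

Dose intensity (DI) is the prescribed weekly dose as a percentage of the
BSA-scaled protocol-recommended dose.  Combined dose intensity ("dose
exposure") is the product of the weighted-mean DIs of 6MP and MTX,
normalised so that protocol dosing of both drugs reads 100%.

Aggregation between prescribing visits uses weighted means: the value
recorded at a visit is carried forward over the half-open interval from
that visit to the next (the prescription holds until it is changed), so the
weight of visit *i* is the interval width ``week_{i+1} - week_i``; the last
visit carries to the end of the course, floored at one week.  A cycle
summary splits an interval spanning a 12-week cycle boundary between the
two cycles, which makes the cycle decomposition conserve the whole-course
weighted mean exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .model import PatientCourse, ProtocolRules

__all__ = [
    "WeightedSeries",
    "CycleSummary",
    "PatientSummary",
    "CohortSummary",
    "ComparisonReport",
    "interval_weights",
    "weighted_mean",
    "dose_intensity",
    "combined_intensity",
    "visit_intensities",
    "summarize_cycles",
    "summarize_course",
    "time_in_target",
    "anc_band_percentages",
    "summarize_cohort",
    "compare_cohorts",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going up (38 from 37.5)."""
    return int(math.floor(x + 0.5))


@dataclass
class WeightedSeries:
    """An interval-weighted series of visit values."""

    weeks: Sequence[float]
    values: Sequence[Optional[float]]
    weights: Sequence[float]

    def __post_init__(self) -> None:
        if not (len(self.weeks) == len(self.values) == len(self.weights)):
            raise ValueError("weeks, values and weights must have equal length")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")


@dataclass
class CycleSummary:
    cycle_index: int  # 1-based
    wm_anc: Optional[float]
    wm_di_mp: float
    wm_di_mtx: float
    wm_di_combined: float
    n_visits: int
    total_weight: float = 0.0  # weeks of interval mass assigned to the cycle


@dataclass
class PatientSummary:
    patient_id: str
    wm_anc: Optional[float]
    wm_di_mp: float
    wm_di_mtx: float
    wm_di_combined: float
    time_in_target_pct: float
    above_di_threshold: bool
    in_anc_target: bool


@dataclass
class CohortSummary:
    summaries: list[PatientSummary]
    n_above_di_threshold: int
    n_above_di_in_anc_target: int
    failed: list[str] = field(default_factory=list)  # patient ids that errored


@dataclass
class ComparisonReport:
    labels: tuple[str, str]
    groups: tuple[list[PatientSummary], list[PatientSummary]]
    tests: dict[str, tuple[float, float]]  # metric -> (statistic, p-value)
    n_above_di: tuple[int, int]
    method: str


# ---------------------------------------------------------------------------
# primitives


def interval_weights(weeks: Sequence[float], end_week: float) -> list[float]:
    """Forward-carry interval widths for a strictly increasing visit grid.

    ``weight_i = week_{i+1} - week_i`` for all but the last visit, whose
    weight is ``end_week - week_n`` floored at one week (a prescription is
    assumed to hold for at least one week).
    """
    weeks = list(weeks)
    if not weeks:
        raise ValueError("empty visit series")
    for a, b in zip(weeks, weeks[1:]):
        if b <= a:
            raise ValueError(f"weeks must be strictly increasing, got {a} then {b}")
    if end_week < weeks[-1]:
        raise ValueError(f"end_week {end_week} precedes last visit week {weeks[-1]}")
    w = [b - a for a, b in zip(weeks, weeks[1:])]
    w.append(max(end_week - weeks[-1], 1.0))
    return w


def weighted_mean(series: WeightedSeries) -> float:
    """Sum(w_i v_i) / Sum(w_i) over the non-missing entries.

    Missing values are dropped together with their weights; an all-missing
    series is an error.
    """
    num = den = 0.0
    for v, w in zip(series.values, series.weights):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        num += w * v
        den += w
    if den == 0:
        raise ValueError("weighted_mean: no non-missing values with positive weight")
    return num / den


def dose_intensity(
    dose: float, protocol_per_m2: float, bsa: float, drug: str
) -> float:
    """Prescribed dose as % of the BSA-scaled protocol dose.

    ``drug`` selects the protocol-dose convention: 6MP ("MP") protocols
    state mg/m^2/day, so the weekly protocol dose is ``daily x 7 x BSA``;
    MTX protocols state mg/m^2/week, so it is ``weekly x BSA``.
    """
    if dose < 0:
        raise ValueError(f"negative dose {dose}")
    if bsa <= 0 or protocol_per_m2 <= 0:
        raise ValueError("bsa and protocol dose must be positive")
    drug = drug.upper()
    if drug == "MP":
        protocol_weekly = protocol_per_m2 * 7.0 * bsa
    elif drug == "MTX":
        protocol_weekly = protocol_per_m2 * bsa
    else:
        raise ValueError(f"unknown drug {drug!r} (expected 'MP' or 'MTX')")
    return 100.0 * dose / protocol_weekly


def combined_intensity(wm_di_mp: float, wm_di_mtx: float) -> float:
    """Product of the two weighted-mean DIs, normalised so 100 x 100 -> 100."""
    if wm_di_mp < 0 or wm_di_mtx < 0:
        raise ValueError("dose intensities must be non-negative")
    return wm_di_mp * wm_di_mtx / 100.0


def visit_intensities(course: PatientCourse, rules: ProtocolRules) -> tuple[list[float], list[float]]:
    """Per-visit (DI_mp, DI_mtx) in %, using each visit's own BSA."""
    di_mp = [
        dose_intensity(v.mp_dose, rules.mp_protocol_daily, v.bsa, "MP")
        for v in course.visits
    ]
    di_mtx = [
        dose_intensity(v.mtx_dose, rules.mtx_protocol_weekly, v.bsa, "MTX")
        for v in course.visits
    ]
    return di_mp, di_mtx


# ---------------------------------------------------------------------------
# course summaries


def _course_weights(course: PatientCourse, end_week: Optional[float] = None) -> list[float]:
    end = end_week if end_week is not None else course.mt_end_week
    return interval_weights(course.weeks, max(end, course.visits[-1].week))


def _split_by_cycles(
    weeks: Sequence[float],
    weights: Sequence[float],
    cycle_length: float,
    n_cycles: int,
) -> list[list[tuple[int, float]]]:
    """For each cycle, the (visit index, within-cycle weight) pairs.

    The interval carried by visit *i*, ``[week_i, week_i + weight_i)``, is
    intersected with each cycle window ``[L(k), L(k)+cycle_length)``; mass
    outside the last cycle is assigned to it so nothing is lost when a
    course runs slightly past the nominal end.
    """
    per_cycle: list[list[tuple[int, float]]] = [[] for _ in range(n_cycles)]
    for i, (wk, wt) in enumerate(zip(weeks, weights)):
        lo, hi = wk, wk + wt
        for k in range(n_cycles):
            c_lo = cycle_length * k
            c_hi = cycle_length * (k + 1) if k < n_cycles - 1 else math.inf
            overlap = min(hi, c_hi) - max(lo, c_lo)
            if overlap > 0:
                per_cycle[k].append((i, overlap))
    return per_cycle


def summarize_cycles(
    course: PatientCourse, rules: Optional[ProtocolRules] = None
) -> list[CycleSummary]:
    """Cycle-specific summary measures: weighted-mean ANC and DI per cycle.

    Only cycles containing at least one visit (or carried interval mass)
    are returned.  Cycle *k* covers weeks ``[cycle_length*(k-1),
    cycle_length*k)``; interval weights are split at cycle boundaries.
    """
    rules = rules or ProtocolRules()
    weights = _course_weights(course)
    weeks = course.weeks
    di_mp, di_mtx = visit_intensities(course, rules)
    anc = [v.anc for v in course.visits]
    per_cycle = _split_by_cycles(weeks, weights, rules.cycle_length, rules.n_cycles)

    out: list[CycleSummary] = []
    for k, pairs in enumerate(per_cycle):
        if not pairs:
            continue
        idx = [i for i, _ in pairs]
        w = [wt for _, wt in pairs]
        wm_mp = weighted_mean(WeightedSeries(idx, [di_mp[i] for i in idx], w))
        wm_mtx = weighted_mean(WeightedSeries(idx, [di_mtx[i] for i in idx], w))
        anc_vals = [anc[i] for i in idx]
        wm_anc = (
            weighted_mean(WeightedSeries(idx, anc_vals, w))
            if any(a is not None for a in anc_vals)
            else None
        )
        c_lo = rules.cycle_length * k
        n_visits = sum(1 for wk in weeks if c_lo <= wk < c_lo + rules.cycle_length)
        out.append(
            CycleSummary(
                cycle_index=k + 1,
                wm_anc=wm_anc,
                wm_di_mp=wm_mp,
                wm_di_mtx=wm_mtx,
                wm_di_combined=combined_intensity(wm_mp, wm_mtx),
                n_visits=n_visits,
                total_weight=sum(w),
            )
        )
    return out


def time_in_target(
    course: PatientCourse, rules: Optional[ProtocolRules] = None
) -> float:
    """Percentage of course time with ANC inside the target range.

    The numerator is the total interval weight of visits whose ANC lies in
    ``anc_target_range`` (closed interval); the denominator is the total
    weight of all visits, so weeks without an ANC measurement count as
    out-of-target time.  Returns an exact percentage; reports round half-up
    to the nearest whole percent.
    """
    rules = rules or ProtocolRules()
    weights = _course_weights(course)
    lo, hi = rules.anc_target_range
    if all(v.anc is None for v in course.visits):
        raise ValueError("time_in_target: course has no ANC values")
    in_target = sum(
        w for v, w in zip(course.visits, weights)
        if v.anc is not None and lo <= v.anc <= hi
    )
    return 100.0 * in_target / sum(weights)


def anc_band_percentages(
    course: PatientCourse, rules: Optional[ProtocolRules] = None
) -> dict[str, float]:
    """Exact % of course time with ANC below / in / above the target range.

    Weeks without an ANC measurement are reported separately under
    ``"unmeasured"``; the four percentages sum to 100.
    """
    rules = rules or ProtocolRules()
    weights = _course_weights(course)
    lo, hi = rules.anc_target_range
    total = sum(weights)
    bands = {"below": 0.0, "in": 0.0, "above": 0.0, "unmeasured": 0.0}
    for v, w in zip(course.visits, weights):
        if v.anc is None:
            bands["unmeasured"] += w
        elif v.anc < lo:
            bands["below"] += w
        elif v.anc > hi:
            bands["above"] += w
        else:
            bands["in"] += w
    return {k: 100.0 * v / total for k, v in bands.items()}


def summarize_course(
    course: PatientCourse, rules: Optional[ProtocolRules] = None
) -> PatientSummary:
    """Whole-course weighted means and target flags for one patient."""
    rules = rules or ProtocolRules()
    weights = _course_weights(course)
    weeks = course.weeks
    di_mp, di_mtx = visit_intensities(course, rules)
    wm_mp = weighted_mean(WeightedSeries(weeks, di_mp, weights))
    wm_mtx = weighted_mean(WeightedSeries(weeks, di_mtx, weights))
    anc_vals = [v.anc for v in course.visits]
    wm_anc = (
        weighted_mean(WeightedSeries(weeks, anc_vals, weights))
        if any(a is not None for a in anc_vals)
        else None
    )
    combined = combined_intensity(wm_mp, wm_mtx)
    lo, hi = rules.anc_target_range
    try:
        tit = time_in_target(course, rules)
    except ValueError:
        tit = 0.0
    return PatientSummary(
        patient_id=course.patient_id,
        wm_anc=wm_anc,
        wm_di_mp=wm_mp,
        wm_di_mtx=wm_mtx,
        wm_di_combined=combined,
        time_in_target_pct=tit,
        above_di_threshold=combined >= rules.di_threshold,
        in_anc_target=wm_anc is not None and lo <= wm_anc <= hi,
    )


# ---------------------------------------------------------------------------
# cohorts


def summarize_cohort(
    courses: Iterable[PatientCourse], rules: Optional[ProtocolRules] = None
) -> CohortSummary:
    """Per-patient summaries plus counts against the DI and ANC targets.

    Courses that fail to summarise are listed in ``failed`` and excluded;
    they do not abort the cohort run.
    """
    rules = rules or ProtocolRules()
    summaries: list[PatientSummary] = []
    failed: list[str] = []
    for course in courses:
        try:
            summaries.append(summarize_course(course, rules))
        except Exception:  # noqa: BLE001 - cohort run continues past bad files
            failed.append(course.patient_id)
    if not summaries and failed:
        raise ValueError("no course in the cohort could be summarised")
    n_above = sum(s.above_di_threshold for s in summaries)
    n_above_in_target = sum(
        s.above_di_threshold and s.in_anc_target for s in summaries
    )
    return CohortSummary(summaries, n_above, n_above_in_target, failed)


_TESTS: dict[str, Callable] = {
    "ranksum": lambda a, b: stats.mannwhitneyu(a, b, alternative="two-sided"),
    "ttest": lambda a, b: stats.ttest_ind(a, b, equal_var=False),
}


def compare_cohorts(
    courses: Sequence[PatientCourse],
    rules: Optional[ProtocolRules] = None,
    *,
    intervention_date=None,
    groups: Optional[dict[str, str]] = None,
    method: str = "ranksum",
    labels: tuple[str, str] = ("pre", "post"),
) -> ComparisonReport:
    """Two-group comparison of treatment intensity.

    Patients are split either by MT start date against ``intervention_date``
    (strictly earlier start -> first group) or by an explicit
    ``patient_id -> label`` mapping with exactly two labels.  The default
    test is the two-sided Wilcoxon rank-sum applied to the weighted-mean
    ANC and combined DI of each group.
    """
    rules = rules or ProtocolRules()
    if (intervention_date is None) == (groups is None):
        raise ValueError("provide exactly one of intervention_date or groups")

    assignment: dict[str, int] = {}
    if intervention_date is not None:
        for c in courses:
            if c.mt_start is None:
                raise ValueError(f"{c.patient_id}: no MT start date for date split")
            assignment[c.patient_id] = 0 if c.mt_start < intervention_date else 1
    else:
        found = sorted(set(groups.values()))
        if len(found) != 2:
            raise ValueError(f"group file must define exactly 2 groups, got {found}")
        labels = (found[0], found[1])
        for c in courses:
            if c.patient_id not in groups:
                raise ValueError(f"{c.patient_id}: not assigned to a group")
            assignment[c.patient_id] = found.index(groups[c.patient_id])

    split: tuple[list[PatientSummary], list[PatientSummary]] = ([], [])
    for c in courses:
        split[assignment[c.patient_id]].append(summarize_course(c, rules))
    if not split[0] or not split[1]:
        raise ValueError("each comparison group needs at least one patient")

    if method not in _TESTS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_TESTS)}")
    test = _TESTS[method]
    tests: dict[str, tuple[float, float]] = {}
    for metric, getter in (
        ("wm_anc", lambda s: s.wm_anc),
        ("wm_di_combined", lambda s: s.wm_di_combined),
    ):
        a = [getter(s) for s in split[0] if getter(s) is not None]
        b = [getter(s) for s in split[1] if getter(s) is not None]
        res = test(a, b)
        tests[metric] = (float(res.statistic), float(res.pvalue))

    n_above = tuple(sum(s.above_di_threshold for s in g) for g in split)
    return ComparisonReport(labels, split, tests, n_above, method)
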