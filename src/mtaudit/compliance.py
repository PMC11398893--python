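"""Prescriber compliance audit against STOP / REDUCE / INCREASE rules.

The protocol expects, at each prescribing visit:

* **STOP** — suspend both drugs when ANC < ``anc_stop`` and/or
  PLT < ``plt_stop`` (and Hb < ``hb_stop`` when configured);
* **REDUCE** — halve doses when ANC or PLT sits in the band just above the
  stop threshold (``anc_reduce_range`` / ``plt_reduce_range``);
* **INCREASE** — escalate 6MP by ``escalation_factor`` when every observed
  count over the trailing ``tolerated_dose_duration`` weeks met the
  escalation thresholds on an unchanged BSA-normalised 6MP dose;
* **MAINTAIN** otherwise.

What the prescriber actually did is classified from consecutive dose
prescriptions: both doses zero is a stop; a BSA-normalised 6MP step of at
least ``1 + escalation_factor - step_tolerance`` relative to the running
reference dose is an increase; a step down to at most
``reduction_factor + step_tolerance`` is a reduction.  The reference dose
is the last non-zero normalised dose, so a post-stop resumption at the
previous dose is not misread as an escalation.  Audits compare the two
classifications visit by visit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times

from .model import PatientCourse, ProtocolRules, VisitRecord

__all__ = [
    "STOP", "REDUCE", "MAINTAIN", "INCREASE", "UNEVALUABLE",
    "DecisionEngine",
    "expected_decision",
    "expected_decisions",
    "observed_decision",
    "observed_decisions",
    "RuleAudit",
    "audit_rule",
    "audit_all",
    "EventTime",
    "time_to_first_increase",
    "MedianEstimate",
    "km_median",
]

STOP = "STOP"
REDUCE = "REDUCE"
MAINTAIN = "MAINTAIN"
INCREASE = "INCREASE"
UNEVALUABLE = "UNEVALUABLE"

AUDITED_RULES = (STOP, REDUCE, INCREASE)


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


class DecisionEngine:
    """Stateful rule engine emitting the protocol-expected decision per visit.

    Visits must be fed in week order.  The INCREASE eligibility window
    tracks the run of qualifying observed counts on a stable normalised
    6MP dose; it resets on any dose change, any sub-threshold count, and —
    under the default ``reset_on_opportunity`` policy — after each counted
    opportunity.  Under the ``sliding`` policy consecutive qualifying
    weeks each count as an opportunity.
    """

    def __init__(self, rules: ProtocolRules):
        self.rules = rules
        self._streak_start: Optional[float] = None
        self._streak_dose: Optional[float] = None

    def _counts_qualify(self, v: VisitRecord) -> bool:
        r = self.rules
        if _missing(v.anc) and _missing(v.plt):
            return False  # a streak needs at least one observed count
        if not _missing(v.anc) and v.anc < r.anc_increase:
            return False
        if not _missing(v.plt) and v.plt < r.plt_increase:
            return False
        return True

    def evaluate(self, visit: VisitRecord) -> str:
        """Expected decision at ``visit`` from its counts and the current window.

        Does not mutate the window; the dose the prescriber then writes is
        folded in afterwards via :meth:`commit`.
        """
        r = self.rules
        anc, plt, hb = visit.anc, visit.plt, visit.hb
        evaluable = not (_missing(anc) and _missing(plt)
                         and (r.hb_stop is None or _missing(hb)))
        if not evaluable:
            return UNEVALUABLE
        stop = (
            (not _missing(anc) and anc < r.anc_stop)
            or (not _missing(plt) and plt < r.plt_stop)
            or (r.hb_stop is not None and not _missing(hb) and hb < r.hb_stop)
        )
        reduce_ = (
            (not _missing(anc)
             and r.anc_reduce_range[0] <= anc < r.anc_reduce_range[1])
            or (not _missing(plt)
                and r.plt_reduce_range[0] <= plt < r.plt_reduce_range[1])
        )
        if stop:
            return STOP
        if reduce_:
            return REDUCE
        if (
            self._streak_start is not None
            and self._counts_qualify(visit)
            and visit.week - self._streak_start >= r.tolerated_dose_duration
        ):
            return INCREASE
        return MAINTAIN

    def commit(self, visit: VisitRecord, decision: str) -> None:
        """Fold the visit's counts and newly prescribed dose into the window."""
        r = self.rules
        norm_mp = visit.mp_dose / visit.bsa
        evaluable = decision != UNEVALUABLE
        if decision == INCREASE and r.increase_window_policy == "reset_on_opportunity":
            self._streak_start, self._streak_dose = visit.week, norm_mp
        if evaluable and not self._counts_qualify(visit):
            self._streak_start = self._streak_dose = None
        elif norm_mp <= 0:
            # no dose is being tolerated while treatment is suspended
            self._streak_start = self._streak_dose = None
        elif self._streak_start is None:
            if self._counts_qualify(visit):
                self._streak_start, self._streak_dose = visit.week, norm_mp
        elif not math.isclose(norm_mp, self._streak_dose,
                              rel_tol=self.rules.step_tolerance):
            self._streak_start, self._streak_dose = visit.week, norm_mp

    def step(self, visit: VisitRecord) -> str:
        """Classify ``visit`` and fold its counts and dose into the window."""
        decision = self.evaluate(visit)
        self.commit(visit, decision)
        return decision


def expected_decisions(
    course: PatientCourse, rules: Optional[ProtocolRules] = None
) -> list[str]:
    """Protocol-expected decision class at every visit of a course."""
    rules = rules or ProtocolRules()
    engine = DecisionEngine(rules)
    return [engine.step(v) for v in course.visits]


def expected_decision(
    visit: VisitRecord,
    history: Sequence[VisitRecord],
    rules: Optional[ProtocolRules] = None,
) -> str:
    """Expected decision at ``visit`` given the trailing visit ``history``."""
    rules = rules or ProtocolRules()
    engine = DecisionEngine(rules)
    for h in history:
        engine.step(h)
    return engine.step(visit)


def observed_decision(
    prev: VisitRecord, cur: VisitRecord, rules: Optional[ProtocolRules] = None
) -> str:
    """Classify the prescriber's actual decision between two visits."""
    rules = rules or ProtocolRules()
    if cur.is_stop:
        return STOP
    ref = prev.mp_dose / prev.bsa
    cur_norm = cur.mp_dose / cur.bsa
    if ref <= 0:
        return MAINTAIN  # resumption after a stop; no magnitude reference
    tol = rules.step_tolerance
    if cur_norm >= ref * (1.0 + rules.escalation_factor - tol):
        return INCREASE
    if 0 < cur_norm <= ref * (rules.reduction_factor + tol):
        return REDUCE
    return MAINTAIN


def observed_decisions(
    course: PatientCourse, rules: Optional[ProtocolRules] = None
) -> list[Optional[str]]:
    """Observed decision per visit; the first visit is baseline (``None``).

    Uses a running post-stop reference dose (the last non-zero normalised
    6MP dose) so that resuming at an unchanged dose after a suspension is
    MAINTAIN, not INCREASE.
    """
    rules = rules or ProtocolRules()
    out: list[Optional[str]] = [None]
    ref: float = course.visits[0].mp_dose / course.visits[0].bsa
    tol = rules.step_tolerance
    for cur in course.visits[1:]:
        cur_norm = cur.mp_dose / cur.bsa
        if cur.is_stop:
            out.append(STOP)
        elif ref <= 0:
            out.append(MAINTAIN)
        elif cur_norm >= ref * (1.0 + rules.escalation_factor - tol):
            out.append(INCREASE)
        elif 0 < cur_norm <= ref * (rules.reduction_factor + tol):
            out.append(REDUCE)
        else:
            out.append(MAINTAIN)
        if cur_norm > 0:
            ref = cur_norm
    return out


@dataclass
class RuleAudit:
    rule: str
    n_expected: int
    n_concordant: int
    n_discretionary: int
    n_observed: int
    n_unevaluable: int
    missed_opportunities: int
    ledger: pd.DataFrame = field(repr=False, default=None)

    @property
    def compliance_pct(self) -> Optional[float]:
        if self.n_expected == 0:
            return None
        return 100.0 * self.n_concordant / self.n_expected

    @property
    def discretionary_pct(self) -> Optional[float]:
        if self.n_observed == 0:
            return None
        return 100.0 * self.n_discretionary / self.n_observed


def _decision_ledger(
    course: PatientCourse, rules: ProtocolRules
) -> pd.DataFrame:
    expected = expected_decisions(course, rules)
    observed = observed_decisions(course, rules)
    rows = []
    for v, e, o in zip(course.visits, expected, observed):
        rows.append(
            {
                "week": v.week,
                "anc": v.anc,
                "plt": v.plt,
                "hb": v.hb,
                "mp_dose": v.mp_dose,
                "mtx_dose": v.mtx_dose,
                "expected": e,
                "observed": o,
                "concordant": (o == e) if o is not None and e != UNEVALUABLE else None,
            }
        )
    return pd.DataFrame(rows)


def audit_rule(
    course: PatientCourse,
    rules: Optional[ProtocolRules] = None,
    rule: str = STOP,
    ledger: Optional[pd.DataFrame] = None,
) -> RuleAudit:
    """Audit one titration rule over a course.

    Denominators: ``compliance_pct`` uses visits where the rule was
    expected (first/baseline and unevaluable visits excluded);
    ``discretionary_pct`` uses all observed decisions of the class.  For
    INCREASE, ``missed_opportunities`` counts expected-but-not-taken
    escalations.
    """
    if rule not in AUDITED_RULES:
        raise ValueError(f"rule must be one of {AUDITED_RULES}, got {rule!r}")
    rules = rules or ProtocolRules()
    df = ledger if ledger is not None else _decision_ledger(course, rules)
    scored = df[df["observed"].notna()]
    n_unevaluable = int((scored["expected"] == UNEVALUABLE).sum())
    evaluable = scored[scored["expected"] != UNEVALUABLE]
    exp_mask = evaluable["expected"] == rule
    obs_mask = evaluable["observed"] == rule
    n_expected = int(exp_mask.sum())
    n_concordant = int((exp_mask & obs_mask).sum())
    n_observed = int(obs_mask.sum())
    n_discretionary = int((obs_mask & ~exp_mask).sum())
    missed = int((exp_mask & ~obs_mask).sum()) if rule == INCREASE else 0
    return RuleAudit(
        rule=rule,
        n_expected=n_expected,
        n_concordant=n_concordant,
        n_discretionary=n_discretionary,
        n_observed=n_observed,
        n_unevaluable=n_unevaluable,
        missed_opportunities=missed,
        ledger=df,
    )


def audit_all(
    course: PatientCourse, rules: Optional[ProtocolRules] = None
) -> dict[str, RuleAudit]:
    """Audit STOP, REDUCE and INCREASE on a shared per-visit ledger."""
    rules = rules or ProtocolRules()
    df = _decision_ledger(course, rules)
    return {r: audit_rule(course, rules, r, ledger=df) for r in AUDITED_RULES}


# ---------------------------------------------------------------------------
# time to first dose increase


@dataclass(frozen=True)
class EventTime:
    patient_id: str
    weeks_to_first_increase: float
    censored: bool


def time_to_first_increase(
    course: PatientCourse, rules: Optional[ProtocolRules] = None
) -> EventTime:
    """Week of the first observed 6MP escalation, censored at MT end."""
    rules = rules or ProtocolRules()
    observed = observed_decisions(course, rules)
    for v, o in zip(course.visits, observed):
        if o == INCREASE:
            return EventTime(course.patient_id, v.week, censored=False)
    return EventTime(course.patient_id, course.mt_end_week, censored=True)


@dataclass
class MedianEstimate:
    median_weeks: Optional[float]  # None when the curve never reaches 0.5
    ci_low_weeks: Optional[float]
    ci_high_weeks: Optional[float]


def _finite_or_none(x) -> Optional[float]:
    x = float(x)
    return None if not math.isfinite(x) else x


def km_median(
    events: Sequence[EventTime],
) -> tuple[MedianEstimate, pd.DataFrame]:
    """Product-limit median time to first dose increase with 95% CI.

    Censored records (no escalation by MT end) enter as right-censored.
    The median is the first week at which the survival curve drops to or
    below 0.5; confidence bounds use the log-log transform and may be
    non-evaluable (``None``) when the curve never crosses the limit.
    Also returns the survival table (week, at-risk, events, survival).
    """
    if not events:
        raise ValueError("km_median needs at least one event record")
    durations = [e.weeks_to_first_increase for e in events]
    observed = [0 if e.censored else 1 for e in events]
    kmf = KaplanMeierFitter(alpha=0.05)
    kmf.fit(durations, event_observed=observed)

    # first week where survival reaches 0.5; tolerance absorbs float error in
    # the product-limit so exact ties (S = 1/2 from non-dyadic factors) count
    sf = kmf.survival_function_["KM_estimate"]
    crossed = sf[sf <= 0.5 + 1e-9]
    median = float(crossed.index[0]) if len(crossed) else None
    ci_df = median_survival_times(kmf.confidence_interval_)
    ci_low = _finite_or_none(ci_df.iloc[0, 0])
    ci_high = _finite_or_none(ci_df.iloc[0, 1])

    table = kmf.event_table.copy()
    table["survival"] = kmf.survival_function_["KM_estimate"]
    table = table.reset_index().rename(
        columns={"event_at": "week", "at_risk": "n_at_risk", "observed": "n_events"}
    )[["week", "n_at_risk", "n_events", "censored", "survival"]]
    return MedianEstimate(median, ci_low, ci_high), table
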