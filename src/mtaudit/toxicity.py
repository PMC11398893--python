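"""Cytopenia episode detection and hematological toxicity reports.

An episode is a maximal run of consecutive *observed* visits with a blood
count strictly below its threshold (e.g. neutropenia: ANC < 0.5 x 10^9/L).
Missing values are non-observations: they neither break nor extend a run.
Episode duration is anchored to recovery — it runs from the first
below-threshold visit to the first subsequent observed visit at or above
the threshold, or to the end of observation for an unrecovered terminal
episode — matching the clinical notion of weeks of treatment suspension.
Episodes lasting at least ``long_episode_weeks`` (default 3) are flagged as
long.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .intensity import interval_weights
from .model import PatientCourse, ProtocolRules

__all__ = [
    "Episode",
    "AnalyteToxicity",
    "ToxicityReport",
    "detect_episodes",
    "toxicity_report",
    "cohort_toxicity",
]

ANALYTES = ("anc", "plt", "hb")


@dataclass(frozen=True)
class Episode:
    analyte: str
    start_week: float
    recovery_week: float  # first at-or-above-threshold visit, or end of observation
    is_long: bool = False

    @property
    def duration_weeks(self) -> float:
        return self.recovery_week - self.start_week


@dataclass
class AnalyteToxicity:
    analyte: str
    threshold: float
    episodes: list[Episode] = field(default_factory=list)

    @property
    def n_episodes(self) -> int:
        return len(self.episodes)

    @property
    def cumulative_weeks(self) -> float:
        return sum(e.duration_weeks for e in self.episodes)

    @property
    def n_long_episodes(self) -> int:
        return sum(e.is_long for e in self.episodes)

    @property
    def cumulative_long_weeks(self) -> float:
        return sum(e.duration_weeks for e in self.episodes if e.is_long)


@dataclass
class ToxicityReport:
    patient_id: str
    per_analyte: dict[str, AnalyteToxicity]
    interruption_weeks: float  # interval weight with both doses prescribed as 0
    below_threshold_weeks: float  # union-free sum of per-analyte episode weeks

    def counts(self) -> dict[str, dict[str, float]]:
        """Nested dict of the headline numbers, for JSON reports."""
        return {
            a: {
                "threshold": t.threshold,
                "n_episodes": t.n_episodes,
                "cumulative_weeks": t.cumulative_weeks,
                "n_long_episodes": t.n_long_episodes,
                "cumulative_long_weeks": t.cumulative_long_weeks,
            }
            for a, t in self.per_analyte.items()
        }


def _observed(weeks: Sequence[float], values: Sequence[Optional[float]]):
    for w, v in zip(weeks, values):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        yield w, v


def detect_episodes(
    weeks: Sequence[float],
    values: Sequence[Optional[float]],
    threshold: float,
    *,
    analyte: str = "anc",
    end_week: Optional[float] = None,
    long_episode_weeks: float = 3.0,
) -> list[Episode]:
    """Find maximal below-threshold runs in an observed count series.

    ``end_week`` bounds the duration of an unrecovered terminal episode
    (defaults to the last observed week).  Episodes are disjoint, ordered,
    and never merged across a recovered visit.
    """
    obs = list(_observed(weeks, values))
    if not obs:
        return []
    if end_week is None:
        end_week = obs[-1][0]

    episodes: list[Episode] = []
    start: Optional[float] = None
    for w, v in obs:
        if v < threshold:
            if start is None:
                start = w
        else:
            if start is not None:
                episodes.append(Episode(analyte, start, w))
                start = None
    if start is not None:
        episodes.append(Episode(analyte, start, max(end_week, start)))

    return [
        Episode(e.analyte, e.start_week, e.recovery_week,
                is_long=e.duration_weeks >= long_episode_weeks)
        for e in episodes
    ]


def toxicity_report(
    course: PatientCourse, rules: Optional[ProtocolRules] = None
) -> ToxicityReport:
    """Per-analyte episode summary plus treatment-interruption weeks.

    Thresholds come from the STOP rules (``anc_stop``, ``plt_stop`` and,
    when configured, ``hb_stop``).  Interruption weeks are the interval
    weights of visits where both drug doses are zero — discretionary stops
    count even when no count is below threshold.
    """
    rules = rules or ProtocolRules()
    thresholds = {"anc": rules.anc_stop, "plt": rules.plt_stop}
    if rules.hb_stop is not None:
        thresholds["hb"] = rules.hb_stop

    weeks = course.weeks
    end = max(course.mt_end_week, weeks[-1])
    per_analyte: dict[str, AnalyteToxicity] = {}
    for analyte, thr in thresholds.items():
        eps = detect_episodes(
            weeks,
            course.values(analyte),
            thr,
            analyte=analyte,
            end_week=end,
            long_episode_weeks=rules.long_episode_weeks,
        )
        per_analyte[analyte] = AnalyteToxicity(analyte, thr, eps)

    weights = interval_weights(weeks, end)
    interruption = sum(
        w for v, w in zip(course.visits, weights) if v.is_stop
    )
    below = sum(t.cumulative_weeks for t in per_analyte.values())
    return ToxicityReport(course.patient_id, per_analyte, interruption, below)


def cohort_toxicity(
    courses: Iterable[PatientCourse], rules: Optional[ProtocolRules] = None
) -> tuple[dict[str, dict[str, float]], pd.DataFrame]:
    """Cohort totals per analyte plus the per-patient breakdown table."""
    rules = rules or ProtocolRules()
    rows = []
    for course in courses:
        rep = toxicity_report(course, rules)
        for analyte, tox in rep.per_analyte.items():
            rows.append(
                {
                    "patient_id": rep.patient_id,
                    "analyte": analyte,
                    "n_episodes": tox.n_episodes,
                    "cumulative_weeks": tox.cumulative_weeks,
                    "n_long_episodes": tox.n_long_episodes,
                    "cumulative_long_weeks": tox.cumulative_long_weeks,
                    "interruption_weeks": rep.interruption_weeks,
                }
            )
    table = pd.DataFrame(rows)
    totals: dict[str, dict[str, float]] = {}
    if not table.empty:
        agg = table.groupby("analyte")[
            ["n_episodes", "cumulative_weeks", "n_long_episodes",
             "cumulative_long_weeks"]
        ].sum()
        totals = {a: row.to_dict() for a, row in agg.iterrows()}
    return totals, table
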