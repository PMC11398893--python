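"""Core data model for maintenance-therapy (MT) titration auditing.

A patient's MT course is an ordered sequence of prescribing visits.  At each
visit the prescriber records the blood counts used to titrate therapy
(absolute neutrophil count, platelet count, hemoglobin), the patient's body
surface area, and the oral antimetabolite doses prescribed until the next
visit: 6-mercaptopurine (6MP) and methotrexate (MTX), both in mg/week.

All counts are stored in canonical units: ANC and PLT in 10^9/L, Hb in g/dL.
Weeks are 0-based from the start of maintenance; all intervals are half-open
``[start, end)``.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml

__all__ = [
    "VisitRecord",
    "PatientCourse",
    "ProtocolRules",
    "ValidationIssue",
    "ValidationReport",
    "CANONICAL_COLUMNS",
]

#: Column order of the canonical per-patient CSV dialect.
CANONICAL_COLUMNS = (
    "patient_id",
    "date",
    "week",
    "bsa",
    "anc",
    "plt",
    "hb",
    "mp_dose",
    "mtx_dose",
)


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class VisitRecord:
    """One prescribing visit.

    Parameters
    ----------
    week:
        Weeks since MT start (0-based, may be fractional).
    bsa:
        Body surface area in m^2; protocol doses are scaled by this value.
    anc, plt, hb:
        Blood counts in canonical units (ANC, PLT: 10^9/L; Hb: g/dL).
        Any may be missing at a given visit, but not all three.
    mp_dose, mtx_dose:
        Prescribed 6MP / MTX in mg per week.  Both zero encodes a
        treatment stop.
    date:
        Calendar date of the visit, if known.
    """

    week: float
    bsa: float
    mp_dose: float
    mtx_dose: float
    anc: Optional[float] = None
    plt: Optional[float] = None
    hb: Optional[float] = None
    date: Optional[_dt.date] = None

    @property
    def is_stop(self) -> bool:
        """True when both drugs are withheld (treatment stop)."""
        return self.mp_dose == 0 and self.mtx_dose == 0

    def has_any_count(self) -> bool:
        return not (
            _is_missing(self.anc) and _is_missing(self.plt) and _is_missing(self.hb)
        )


@dataclass
class PatientCourse:
    """An ordered maintenance course for one patient."""

    patient_id: str
    visits: list[VisitRecord]
    mt_end_week: float = 96.0
    mt_start: Optional[_dt.date] = None

    def __post_init__(self) -> None:
        if not self.visits:
            raise ValueError(f"course {self.patient_id!r} has no visits")

    @property
    def weeks(self) -> list[float]:
        return [v.week for v in self.visits]

    def values(self, analyte: str) -> list[Optional[float]]:
        """Per-visit values of ``analyte`` (one of anc/plt/hb/mp_dose/mtx_dose)."""
        return [getattr(v, analyte) for v in self.visits]

    def __len__(self) -> int:
        return len(self.visits)


@dataclass
class ProtocolRules:
    """All thresholds and factors governing titration and its audit.

    Defaults follow a typical pediatric ALL maintenance protocol: treatment
    is stopped when ANC < 0.5 x 10^9/L or PLT < 50 x 10^9/L, doses are
    halved in the band just above those thresholds, and 6MP is escalated by
    10% after 8 consecutive weeks of adequate counts on a stable dose.
    """

    # protocol-recommended doses per m^2
    mp_protocol_daily: float = 60.0  # mg/m^2/day
    mtx_protocol_weekly: float = 20.0  # mg/m^2/week

    # STOP thresholds (counts strictly below trigger suspension)
    anc_stop: float = 0.5
    plt_stop: float = 50.0
    hb_stop: Optional[float] = None

    # REDUCE bands, half-open [low, high)
    anc_reduce_range: tuple[float, float] = (0.5, 0.75)
    plt_reduce_range: tuple[float, float] = (50.0, 75.0)
    reduction_factor: float = 0.5

    # INCREASE rule
    anc_increase: float = 0.75
    plt_increase: float = 75.0
    escalation_factor: float = 0.10
    tolerated_dose_duration: float = 8.0  # weeks of adequate counts on stable dose
    increase_window_policy: str = "reset_on_opportunity"  # or "sliding"

    # targets and reporting
    anc_target_range: tuple[float, float] = (0.75, 1.5)
    di_threshold: float = 80.0  # % combined dose intensity
    long_episode_weeks: float = 3.0
    cycle_length: float = 12.0
    n_cycles: int = 8

    # tolerance for classifying observed dose steps (tablet rounding)
    step_tolerance: float = 0.05

    # multiplier converting input counts to canonical 10^9/L
    count_unit_scale: float = 1.0

    _POLICIES = ("reset_on_opportunity", "sliding")

    def __post_init__(self) -> None:
        if self.increase_window_policy not in self._POLICIES:
            raise ValueError(
                f"increase_window_policy must be one of {self._POLICIES}, "
                f"got {self.increase_window_policy!r}"
            )
        for name in ("mp_protocol_daily", "mtx_protocol_weekly", "anc_stop",
                     "plt_stop", "anc_increase", "plt_increase",
                     "tolerated_dose_duration", "cycle_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("reduction_factor", "escalation_factor"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        for rng, stop in (
            (self.anc_reduce_range, self.anc_stop),
            (self.plt_reduce_range, self.plt_stop),
        ):
            if not rng[0] <= stop or not rng[0] < rng[1]:
                raise ValueError(
                    f"reduce range {rng} must abut its stop threshold {stop}"
                )

    @property
    def mt_length_weeks(self) -> float:
        """Nominal MT duration: cycle_length x n_cycles (96 weeks by default)."""
        return self.cycle_length * self.n_cycles

    def mp_protocol_weekly_dose(self, bsa: float) -> float:
        """Protocol 6MP dose in mg/week for a given BSA (daily dose x 7 x BSA)."""
        return self.mp_protocol_daily * 7.0 * bsa

    def mtx_protocol_weekly_dose(self, bsa: float) -> float:
        """Protocol MTX dose in mg/week for a given BSA."""
        return self.mtx_protocol_weekly * bsa

    # ---- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["anc_reduce_range"] = list(self.anc_reduce_range)
        d["plt_reduce_range"] = list(self.plt_reduce_range)
        d["anc_target_range"] = list(self.anc_target_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolRules":
        kwargs = dict(d)
        for key in ("anc_reduce_range", "plt_reduce_range", "anc_target_range"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ValueError(f"unknown protocol-rule fields: {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "ProtocolRules":
        """Load rules from a YAML or JSON config file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"rules file {path} does not contain a mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        p = Path(path)
        if p.suffix.lower() == ".json":
            p.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        else:
            p.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    visit_index: Optional[int]
    message: str


@dataclass
class ValidationReport:
    patient_id: str
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    @property
    def ok(self) -> bool:
        """True when nothing blocks downstream analysis (warnings allowed)."""
        return not self.errors
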