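"""Shared fixtures: protocol rules and hand-built course constructors."""

from __future__ import annotations

from typing import Optional, Sequence

import pytest

from mtaudit.model import PatientCourse, ProtocolRules, VisitRecord


@pytest.fixture
def rules() -> ProtocolRules:
    return ProtocolRules()


def build_course(
    weeks: Sequence[float],
    anc: Optional[Sequence[Optional[float]]] = None,
    plt: Optional[Sequence[Optional[float]]] = None,
    hb: Optional[Sequence[Optional[float]]] = None,
    mp: Optional[Sequence[float]] = None,
    mtx: Optional[Sequence[float]] = None,
    bsa: float | Sequence[float] = 1.0,
    patient_id: str = "TEST",
    mt_end_week: float = 96.0,
) -> PatientCourse:
    """Course builder with protocol-dose defaults at BSA 1 (6MP 420, MTX 20)."""
    n = len(weeks)

    def seq(x, default):
        if x is None:
            return [default] * n
        return list(x)

    bsas = [bsa] * n if isinstance(bsa, (int, float)) else list(bsa)
    anc = seq(anc, 1.0)
    plt = seq(plt, 200.0)
    hb = seq(hb, None)
    mp = seq(mp, 420.0)
    mtx = seq(mtx, 20.0)
    visits = [
        VisitRecord(week=w, bsa=b, anc=a, plt=p, hb=h, mp_dose=m, mtx_dose=x)
        for w, b, a, p, h, m, x in zip(weeks, bsas, anc, plt, hb, mp, mtx)
    ]
    return PatientCourse(patient_id=patient_id, visits=visits,
                         mt_end_week=mt_end_week)


@pytest.fixture
def protocol_course() -> PatientCourse:
    """96 weekly visits at exact protocol doses, ANC constant at 1.0."""
    return build_course(list(range(96)))
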