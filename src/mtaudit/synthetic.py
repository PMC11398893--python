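"""Seeded generator of synthetic maintenance courses and cohorts.

The generator is a deliberately minimal mechanistic model whose only job is
to produce the three titration regimes seen in practice — serial
up-titration to tolerance, absent titration, and toxicity-driven
down-titration — with counts that respond to dose and a prescriber whose
rule compliance is imperfect.

Blood counts follow a static exponential dose-response with multiplicative
lognormal noise::

    count_t = baseline * exp(-k * DI_t / 100) * LogNormal(0, sigma)

where ``DI_t`` is the combined antimetabolite dose intensity of the
prescription in effect since the previous visit and ``k`` is the patient's
myelosuppression sensitivity (hypersensitive k > standard k > hyposensitive
k).  The prescriber evaluates the protocol rule engine at every visit and
obeys each expected STOP / REDUCE / INCREASE with its own Bernoulli
probability, otherwise maintaining the current dose; after a suspension,
treatment restarts at ``reduction_factor`` times the pre-stop dose once
counts recover to the escalation thresholds.  Simulated 6MP doses are
rounded to 12.5 mg/week tablet steps (up when escalating, down when
reducing) and MTX to 2.5 mg/week, so dose-step classification tolerances
are exercised.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .compliance import DecisionEngine, INCREASE, MAINTAIN, REDUCE, STOP
from .intensity import combined_intensity, dose_intensity
from .model import PatientCourse, ProtocolRules, VisitRecord

__all__ = [
    "PatientPhenotype",
    "PrescriberModel",
    "PHENOTYPES",
    "simulate_course",
    "simulate_cohort",
    "write_cohort",
]

MP_GRANULE = 12.5  # mg/week; quarter of a 50 mg tablet taken daily
MTX_GRANULE = 2.5  # mg/week


@dataclass(frozen=True)
class PatientPhenotype:
    """Dose-response parameters for one simulated patient.

    ``k`` is the log-linear myelosuppression slope per unit combined dose
    intensity; ``noise_sigma`` the log-scale SD of week-to-week count
    variation on a stable dose.
    """

    label: str = "standard"
    baseline_anc: float = 3.0  # 10^9/L, off-treatment neutrophil count
    baseline_plt: float = 300.0  # 10^9/L
    baseline_hb: float = 12.0  # g/dL
    k: float = 0.65
    k_plt_ratio: float = 0.3  # platelet sensitivity relative to ANC
    k_hb_ratio: float = 0.1
    noise_sigma: float = 0.15
    noise_sigma_other: float = 0.10  # PLT and Hb

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("sensitivity k must be > 0")
        if self.noise_sigma < 0 or self.noise_sigma_other < 0:
            raise ValueError("noise sigma must be >= 0")


#: Reference phenotypes for the three titration regimes.  The standard k is
#: calibrated so the maximum tolerated combined DI (where median ANC crosses
#: the escalation threshold, ln(baseline/0.75)/k x 100) sits near 215%, the
#: middle of the 180-240% band a well up-titrated patient reaches; the
#: hypersensitive k puts it near 35% (cannot hold protocol doses at all) and
#: the hyposensitive k near 460% (never count-limited within a course).
PHENOTYPES: dict[str, PatientPhenotype] = {
    "standard": PatientPhenotype(label="standard", k=0.65),
    "hypersensitive": PatientPhenotype(label="hypersensitive", k=4.0),
    "hyposensitive": PatientPhenotype(label="hyposensitive", k=0.3),
}


@dataclass(frozen=True)
class PrescriberModel:
    """Per-rule compliance probabilities and the visit schedule."""

    p_stop: float = 1.0
    p_reduce: float = 1.0
    p_increase: float = 1.0
    visit_interval_weeks: float = 1.0

    def __post_init__(self) -> None:
        for name in ("p_stop", "p_reduce", "p_increase"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.visit_interval_weeks <= 0:
            raise ValueError("visit_interval_weeks must be > 0")


def _round_granule(x: float, granule: float, mode: str) -> float:
    q = x / granule
    if mode == "up":
        n = math.ceil(q - 1e-9)
    elif mode == "down":
        n = math.floor(q + 1e-9)
    else:
        n = math.floor(q + 0.5)
    return max(n, 0) * granule


def _bsa_at(week: float, end_week: float, start: float = 0.8, end: float = 1.0) -> float:
    """Linear pediatric BSA growth over the course (0.8 -> 1.0 m^2 by default)."""
    return start + (end - start) * min(week / end_week, 1.0)


def simulate_course(
    phenotype: PatientPhenotype,
    prescriber: Optional[PrescriberModel] = None,
    rules: Optional[ProtocolRules] = None,
    seed: int = 0,
    patient_id: Optional[str] = None,
) -> PatientCourse:
    """Simulate one maintenance course, deterministic given ``seed``.

    Doses start at the protocol-recommended level (rounded to tablet
    granularity).  At each visit the counts realised under the running
    prescription are drawn, the rule engine's expected decision is
    computed, and the prescriber obeys it with the corresponding
    compliance probability.
    """
    prescriber = prescriber or PrescriberModel()
    rules = rules or ProtocolRules()
    rng = np.random.default_rng(seed)
    end_week = rules.mt_length_weeks
    engine = DecisionEngine(rules)

    bsa0 = _bsa_at(0.0, end_week)
    mp = _round_granule(rules.mp_protocol_weekly_dose(bsa0), MP_GRANULE, "nearest")
    mtx = _round_granule(rules.mtx_protocol_weekly_dose(bsa0), MTX_GRANULE, "nearest")
    prestop_mp, prestop_mtx = mp, mtx

    visits: list[VisitRecord] = []
    week = 0.0
    while week < end_week:
        bsa = _bsa_at(week, end_week)
        # counts respond to the prescription in effect since the last visit
        di_mp = dose_intensity(mp, rules.mp_protocol_daily, bsa, "MP")
        di_mtx = dose_intensity(mtx, rules.mtx_protocol_weekly, bsa, "MTX")
        di = combined_intensity(di_mp, di_mtx)

        def draw(baseline: float, k: float, sigma: float) -> float:
            noise = math.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
            return baseline * math.exp(-k * di / 100.0) * noise

        anc = draw(phenotype.baseline_anc, phenotype.k, phenotype.noise_sigma)
        plt = draw(phenotype.baseline_plt, phenotype.k * phenotype.k_plt_ratio,
                   phenotype.noise_sigma_other)
        hb = draw(phenotype.baseline_hb, phenotype.k * phenotype.k_hb_ratio,
                  phenotype.noise_sigma_other)

        probe = VisitRecord(week=week, bsa=bsa, anc=anc, plt=plt, hb=hb,
                            mp_dose=mp, mtx_dose=mtx)
        decision = engine.evaluate(probe)

        new_mp, new_mtx = mp, mtx
        if decision == STOP and rng.random() < prescriber.p_stop:
            if mp > 0 or mtx > 0:
                prestop_mp, prestop_mtx = mp, mtx
            new_mp = new_mtx = 0.0
        elif decision == REDUCE and mp > 0 and rng.random() < prescriber.p_reduce:
            new_mp = max(_round_granule(mp * rules.reduction_factor, MP_GRANULE, "down"),
                         MP_GRANULE)
            new_mtx = max(_round_granule(mtx * rules.reduction_factor, MTX_GRANULE, "down"),
                          MTX_GRANULE)
        elif decision == INCREASE and rng.random() < prescriber.p_increase:
            new_mp = _round_granule(mp * (1.0 + rules.escalation_factor),
                                    MP_GRANULE, "up")
        elif (
            mp == 0 and mtx == 0
            and decision == MAINTAIN
            and anc >= rules.anc_increase and plt >= rules.plt_increase
        ):
            # restart after a suspension, at a reduced dose
            new_mp = max(_round_granule(prestop_mp * rules.reduction_factor,
                                        MP_GRANULE, "down"), MP_GRANULE)
            new_mtx = max(_round_granule(prestop_mtx * rules.reduction_factor,
                                         MTX_GRANULE, "down"), MTX_GRANULE)

        visit = VisitRecord(week=week, bsa=bsa, anc=anc, plt=plt, hb=hb,
                            mp_dose=new_mp, mtx_dose=new_mtx)
        engine.commit(visit, decision)
        visits.append(visit)
        mp, mtx = new_mp, new_mtx
        week += prescriber.visit_interval_weeks

    pid = patient_id or f"SIM_{seed}"
    return PatientCourse(patient_id=pid, visits=visits, mt_end_week=end_week)


def _mix_counts(mix: dict[str, float], n: int) -> list[str]:
    """Largest-remainder apportionment of n patients across phenotype labels."""
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("phenotype mix proportions must sum to 1")
    items = sorted(mix.items())
    exact = [(label, p * n) for label, p in items]
    counts = {label: int(math.floor(x)) for label, x in exact}
    short = n - sum(counts.values())
    for label, x in sorted(exact, key=lambda t: (t[1] - math.floor(t[1])), reverse=True):
        if short == 0:
            break
        counts[label] += 1
        short -= 1
    labels: list[str] = []
    for label, c in sorted(counts.items()):
        labels.extend([label] * c)
    return labels


def simulate_cohort(
    n: int,
    phenotype_mix: Optional[dict[str, float]] = None,
    prescriber: Optional[PrescriberModel] = None,
    rules: Optional[ProtocolRules] = None,
    seed: int = 0,
) -> tuple[list[PatientCourse], list[dict]]:
    """Simulate ``n`` courses plus ground-truth metadata per patient.

    ``phenotype_mix`` maps phenotype labels (keys of :data:`PHENOTYPES`)
    to proportions summing to 1 (default: all standard).  Per-patient seeds
    are spawned from ``seed`` so cohorts are reproducible and individual
    courses re-simulable in isolation.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    prescriber = prescriber or PrescriberModel()
    rules = rules or ProtocolRules()
    phenotype_mix = phenotype_mix or {"standard": 1.0}
    unknown = set(phenotype_mix) - set(PHENOTYPES)
    if unknown:
        raise ValueError(f"unknown phenotype labels: {sorted(unknown)}")

    labels = _mix_counts(phenotype_mix, n)
    rng = np.random.default_rng(seed)
    labels = [labels[i] for i in rng.permutation(n)]
    child_seeds = [int(s) for s in
                   rng.integers(0, 2**31 - 1, size=n)]

    courses: list[PatientCourse] = []
    truth: list[dict] = []
    for i, (label, child_seed) in enumerate(zip(labels, child_seeds)):
        pid = f"SIM_{seed}_{i:03d}"
        course = simulate_course(PHENOTYPES[label], prescriber, rules,
                                 seed=child_seed, patient_id=pid)
        courses.append(course)
        truth.append(
            {
                "patient_id": pid,
                "phenotype": label,
                "seed": child_seed,
                "prescriber": dataclasses.asdict(prescriber),
            }
        )
    return courses, truth


def write_cohort(
    courses: Sequence[PatientCourse],
    truth: Sequence[dict],
    out_dir: str | Path,
) -> list[Path]:
    """Write canonical CSVs plus a ground-truth JSON sidecar."""
    from .io import write_course  # local import to avoid a cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = [write_course(c, out_dir / f"{c.patient_id}.csv") for c in courses]
    (out_dir / "ground_truth.json").write_text(json.dumps(list(truth), indent=2))
    return paths
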