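# mtaudit — dose-titration auditing for ALL maintenance therapy

During the ~2-year maintenance phase (MT) of childhood acute lymphoblastic
leukemia (ALL), oral 6-mercaptopurine (6MP, daily) and methotrexate (MTX,
weekly) must be titrated — up and down, patient by patient — to the highest
tolerated dose combination, guided by serial blood counts. In practice
titration is hard to do well: prescribers often leave doses flat or only
ever reduce them, and under-dosing raises relapse risk. `mtaudit` turns the
routine data already in the chart (visit dates, body surface area, blood
counts, prescribed mg/week) into quantitative audits of titration practice
for individual patients and whole cohorts, plus a seeded synthetic-course
simulator so every analysis can be exercised without patient data.

## What it computes

**Dose intensity.** At each visit, the prescribed dose as a percentage of
the BSA-scaled protocol dose:
DI₆MP = 100 · dose / (d·7·BSA) for a protocol of d mg/m²/day, and
DI_MTX = 100 · dose / (m·BSA) for m mg/m²/week.

**Interval-weighted means.** A prescription holds until the next visit, so
visit values form a step function over time. Summaries use weighted means
with wᵢ = weekᵢ₊₁ − weekᵢ (last visit carried to week 96, floored at one
week): w̄ = Σwᵢvᵢ / Σwᵢ. **Dose exposure** (combined DI) is the product
of the two weighted-mean intensities, normalised so protocol dosing of
both drugs reads 100%: DI = w̄₆MP · w̄_MTX / 100. Cycle-specific summary
measures (CSSM) apply the same math per 12-week cycle, splitting intervals
at cycle boundaries so the cycle decomposition conserves the whole-course
mean exactly.

**Hematological toxicity.** Cytopenia episodes are maximal runs of
consecutive observed counts below threshold (neutropenia ANC < 0.5,
thrombocytopenia PLT < 50 ×10⁹/L; anemia when an Hb threshold is
configured), with duration measured to the first recovered visit and
episodes ≥ 3 weeks flagged as long; treatment-interruption weeks are the
interval weights of visits with both doses zero.

**Prescriber compliance.** A rule engine derives the protocol-expected
decision at every visit — STOP (ANC < 0.5 and/or PLT < 50), REDUCE by 50%
(ANC 0.5–0.75 and/or PLT 50–75), INCREASE 6MP by 10% (counts ≥ 0.75/≥ 75
for 8 consecutive weeks on a stable BSA-normalised dose), else MAINTAIN —
and compares it with the decision actually observed in the dose sequence.
Reports give per-rule concordance, discretionary decisions (action taken
when no rule applied), and missed escalation opportunities. Time to the
first observed 6MP increase is summarised per cohort with a Kaplan–Meier
product-limit median (censoring at MT end, log-log 95% CI).

## Worked example

Simulate a 20-patient cohort with a fully compliant prescriber, then audit
one patient and the cohort:

```sh
mtaudit simulate --n 20 --seed 11 --out cohort
mtaudit cssm cohort/SIM_11_000.csv --out patient
mtaudit compliance cohort/SIM_11_000.csv --out patient
mtaudit cohort cohort --out cohortrep
mtaudit ttfi cohort --out cohortrep
```

`patient/SIM_11_000_cycles.csv` traces titration to tolerance across the
eight 12-week cycles — combined DI climbs from 95% to a peak of 155% as
6MP is escalated, then collapses in cycle 8 after count-driven reductions:

```
 cycle  wm_anc  wm_di_mp  wm_di_mtx  wm_di_combined  n_visits
     1    1.79    102.67      92.43           94.90        12
     2    1.54    113.83      89.67          102.07        12
     ...
     6    1.15    193.82      80.09          155.24        12
     8    2.36    119.65      38.02           45.49        12
```

The whole-course summary in `patient/SIM_11_000_cssm.json` reads
`wm_di_combined_pct: 116` with `wm_anc: 1.50` — an above-threshold,
in-target course — and the compliance report shows a perfect prescriber:
11 of 11 expected escalations taken (`INCREASE compliance_pct: 100`,
`missed_opportunities: 0`). At cohort level, `cohortrep/cohort.json`
counts 20/20 patients at or above the 80% dose-exposure threshold (13 of
them also in the ANC target band), and `cohortrep/ttfi.json` gives a
median time to first dose increase of 8 weeks — the earliest the 8-week
tolerated-dose rule allows.

Real per-patient workbooks (.xlsx) or canonical CSVs are analysed with the
same subcommands; `mtaudit convert` maps a folder of clinic spreadsheets
onto the canonical dialect (`patient_id,date,week,bsa,anc,plt,hb,mp_dose,
mtx_dose`), and `--unit-scale 0.001` converts counts recorded in cells/µL.
Protocol thresholds are configurable via a YAML/JSON rules file (`--rules`).

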