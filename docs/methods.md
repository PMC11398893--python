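# Methods

This note records the statistical conventions, default parameters, and
design choices behind `mtaudit`, and what the synthetic generator does and
does not emulate.

## Data model and conventions

A maintenance course is an ordered list of prescribing visits. Weeks are
0-based from MT start; every interval is half-open `[start, end)`. When a
file carries only dates, weeks are derived as `floor(days since first
visit / 7)`. Counts are stored canonically (ANC, PLT ×10⁹/L; Hb g/dL);
`count_unit_scale` converts other recording units linearly on read.
Missing individual counts are permitted: they are excluded, together with
their interval weights, from any computation that needs them, and are
never interpolated. Body surface area may change between visits — children
grow over two years — so protocol doses and normalised doses are always
recomputed with the visit's own BSA.

## Interval weighting

The value recorded at visit *i* is carried forward over
`[week_i, week_{i+1})`; the last prescription carries to the course end
(default week 96), floored at one week so a terminal visit is never
weightless. Weighted means over these interval widths are exactly the
time-average of the forward-carry step function, which is what the test
suite verifies against rectangle integration. Cycle summaries intersect
each carried interval with the 12-week cycle windows, so an interval
spanning a boundary contributes its within-cycle portion to each side;
this makes the weight-weighted recombination of cycle means equal the
whole-course mean to 1e-9. Interval mass past the nominal last cycle is
assigned to that cycle rather than dropped. Treatment stops (both doses 0)
enter dose-intensity means as DI = 0: exposure averages are diluted by
suspensions, not blind to them.

Time in the neutrophil target range divides the in-target interval weight
by the **total** course weight (unmeasured weeks count as out-of-target),
because the clinical quantity is "weeks of the course spent in range".
Reported percentages round half-up to the nearest whole percent; internal
values stay exact.

## Toxicity episodes

An episode is a maximal run of consecutive *observed* values strictly
below threshold; recovery requires an observed value at or above it.
Duration is recovery-anchored — from the first low visit to the first
recovered visit, or to the end of observation when unrecovered — matching
"weeks of treatment suspension" rather than a count of low measurements.
Missing values neither break nor extend a run (verified by an
insertion-invariance property test). Interruption weeks are computed from
dose-0 visits independently of count episodes, since discretionary halts
occur without qualifying cytopenia; both quantities are reported.

## Compliance audit

Expected decisions are evaluated in visit order with a stateful window for
the INCREASE rule: an opportunity requires every observed count over the
trailing `tolerated_dose_duration` (8) weeks at or above the escalation
thresholds, a window actually spanning those 8 weeks, a positive and
unchanged BSA-normalised 6MP dose throughout (5% relative tolerance for
tablet rounding), and resets on any dose change or sub-threshold count.
Because the reference toolkits do not state what happens *after* an
uncounted opportunity, the window policy is a config enum:
`reset_on_opportunity` (default — each qualifying 8-week block yields one
opportunity) or `sliding` (every further qualifying week counts). Visits
with no evaluable counts are UNEVALUABLE and excluded from denominators,
but reported.

Observed decisions classify the dose sequence: both doses zero is STOP; a
BSA-normalised 6MP step ≥ `1 + escalation_factor − 0.05` times the running
reference dose is INCREASE; a step to ≤ `reduction_factor + 0.05` of it is
REDUCE. The reference dose is the last non-zero normalised dose, so
resuming a suspended prescription at its previous level reads MAINTAIN,
not INCREASE, and growth-driven mg/week changes on a stable mg/m² dose are
not misread as titration. Raising the escalation factor can only shrink
the set of observed increases (monotonicity is tested).

Concordance (`compliance_pct`) divides rule-concordant visits by
rule-expected visits; discretionary rates divide off-protocol actions by
all observed actions of that class. Time to first increase is anchored to
the *observed* classification. The cohort median uses the product-limit
estimator from `lifelines` (events = first increase, censoring at MT end);
the median is read off the survival table with a small tolerance so exact
S = 1/2 ties count, and the 95% CI uses the log-log transform, reporting
non-evaluable bounds as null rather than failing.

## Synthetic generator

The generator exists to produce the three titration regimes seen in
clinic — up-titration to tolerance, absent titration, toxicity-driven
down-titration — with just enough realism to exercise every audit path.
Counts follow a static exponential dose–response with multiplicative
lognormal noise:

    count_t = baseline · exp(−k · DI_t / 100) · LogNormal(0, σ)

where DI_t is the combined dose intensity of the prescription in effect
since the previous visit. Defaults: baselines ANC 3.0, PLT 300 ×10⁹/L,
Hb 12 g/dL; σ = 0.15 for ANC and 0.10 for PLT/Hb (week-to-week variation
on a stable dose; the model has no pharmacodynamic lag, so σ is residual
noise only); PLT and Hb sensitivities are 0.3× and 0.1× the ANC
sensitivity. The standard phenotype uses k = 0.65, placing the maximum
tolerated combined DI — where median ANC meets the 0.75 escalation
threshold, `ln(baseline/0.75)/k · 100` — near 215%, the middle of the
180–240% band a well up-titrated patient reaches; hypersensitive (k = 4,
emulating e.g. NUDT15-variant intolerance) caps near 35% and cannot hold
protocol doses, hyposensitive (k = 0.3) near 460% and is never
count-limited within a course.

The simulated prescriber runs the same rule engine as the audit and obeys
each expected STOP/REDUCE/INCREASE with its own Bernoulli probability,
otherwise maintaining dose; after a suspension, treatment restarts at
`reduction_factor` × the pre-stop dose once counts recover to the
escalation thresholds (a deliberately conservative, and therefore
discretionary-REDUCE-generating, restart). BSA grows linearly 0.8 → 1.0 m²
across the course. 6MP doses round to 12.5 mg/week (up when escalating,
down when reducing — the clinician errs in the decided direction), MTX to
2.5 mg/week, so step-classification tolerances are genuinely exercised.
All draws come from one `numpy` generator per course; cohorts spawn
per-patient seeds below 2³¹, so identical seeds give bit-identical output.

**What passing tests show, and what they do not.** The generator has no
pharmacokinetics (no 6-TGN/DNA-TG accumulation), no lag between dose
change and count response, no autocorrelated noise, no adherence
variation, no non-hematological toxicity, and visit schedules are exactly
regular. Tests passing on synthetic cohorts therefore demonstrate that
the *audit arithmetic and rule logic* are correct on data with known
ground truth — not that real courses satisfy the model. On real data the
same code paths apply unchanged; only thresholds (the rules file) should
need adjusting between protocols.

## Numerical choices and degenerate inputs

Percent rounding is half-up (`floor(x + 0.5)`), matching printed report
values such as 38% for 36/96 weeks. The last-visit weight floor is 1
week. Strict inequality defines toxicity and rule triggers below
thresholds; recovery and escalation eligibility use ≥. An all-missing
series raises for means, returns an empty list for episode detection, and
classifies UNEVALUABLE for decisions. A cohort median with no events is
reported as non-evaluable, never raised. Comparison tests default to the
two-sided Wilcoxon rank-sum (`scipy.stats.mannwhitneyu`); Welch's t-test
is available via `method="ttest"`. Problem sizes in tests and the
acceptance script (cohorts of 10–25 patients, weekly 96-week courses) are
the package's defaults for fast, reproducible simulation studies.

## Known limitations

Legacy `.xls` workbooks are not readable (the reader supports `.xlsx` and
the canonical CSV; export old files first). The compliance engine audits
the cited titration rules only — protocol amendments with different
windows or factors are expressed through the rules file, not code. Hb
rules are off by default (`hb_stop: null`). No CTCAE grading, no
causal attribution of non-compliance, and no interactive interface: the
CLI and library are the surface.
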