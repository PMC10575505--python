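# Methods

## Problem and scope

`capqual` measures the quality of empiric outpatient antibiotic
prescribing for community-acquired pneumonia (CAP) in adults ≥ 65, using
only administrative claims: physician visit claims with diagnostic codes,
drug dispensations, hospital discharge abstracts and a patient registry.
"Quality" is graded on three axes — agent, average daily dose, duration —
against outpatient CAP guidelines, and deviations are excused when the
patient has a documented clinical justification. No laboratory, allergy
or adherence data are modelled; those are not available in claims.

## Episode construction

Pneumonia-coded visits are chained per patient with a **rolling 14-day
gap**: a visit joins the current episode iff it falls within 14 days of
the previous visit. The alternative `from_index` semantics (14 days from
the first visit) is a config switch; rolling is the default because it is
the convention in Canadian outpatient episode-of-infection work and is
the natural reading of "recurrent visits within 14 days". The index date
is the first visit. Episodes with span > 30 days are chronic and flagged
(`chronic_span`); "exceeded 30 days" is read strictly, so a 30-day span
is kept and 31 is excluded. An episode with a hospital admission in the
inclusive window `[index, end + 5]` is flagged `hospitalized` — the
window includes the episode itself because an intra-episode admission
also implies inpatient treatment. Exclusions are flags, never deletions,
so stage accounting (`total = kept + chronic + hospitalized`) is
assertable and reported in the run manifest. All date arithmetic is in
whole days; same-day events have gap 0.

## Linkage

Candidates for an episode are same-patient dispensations with ATC prefix
`J01` dispensed in `[index, end + 5]` (the linkage follow-up and the
hospitalization-exclusion horizon are independent config values that
happen to share the default 5). The earliest candidate is kept — "first
dispensation" captures empiric choice — with same-day ties broken by
smallest record id (deterministic; the tie rule is not dictated by the
data and is therefore configuration-documented). A dispensation eligible
for two episodes of one patient is assigned to the later-index episode
and a warning logged. Duration of therapy is the dispensed days supply
verbatim; average daily dose is `strength × quantity / days_supply`, with
the convention that combination products carry the amoxicillin-component
strength in `strength_mg`.

## Guideline rules

Shipped defaults encode the first-line outpatient CAP regimens: oral
amoxicillin 1 g BID–TID (bounds 2000–3000 mg/day), amoxicillin-clavulanate
875 mg BID (1750 mg/day, amoxicillin component), and doxycycline 200 mg
day 1 then 100 mg BID days 2–5, collapsed to its 5-day mean of 200 mg/day
because dispensation records carry no day-by-day schedule. Recommended
duration is 5 days for all three, compared exactly (tolerance 0 days,
configurable) since the source guidelines state 5 days; dose bounds are
widened by a relative tolerance (default ±10%) to absorb strength
rounding in real formularies. The entire rule set is YAML-swappable for
other guideline vintages. The source guidelines never print numeric
bounds; the numbers above are derived from the quoted regimens.
Amoxicillin-clavulanate keeps BID dosing only in the upper bound.

## Classification

Ordered decision table over (agent class, dose direction, duration
direction, justification, chronic kidney disease):

1. non-first-line ∧ any justification → clinically appropriate
2. non-first-line ∧ no justification → not recommended
3. first-line ∧ dose within ∧ duration within → guideline adherent
4. first-line ∧ (dose below ∨ duration below) → undertreatment
5. first-line ∧ (dose above ∨ duration above), none below → effective but
   unnecessary

then undertreatment in the presence of CKD is reclassified to clinically
appropriate (renal dosing proxy), whichever axis was subtherapeutic —
the source criterion names renal dysfunction without an axis
restriction. Rule 4 makes any subtherapeutic axis dominate: this both
implements the opposing-direction tie-break (subtherapeutic use is of
higher clinical significance) and resolves the otherwise-unaddressed
both-below case. Unknown agents (no rule, non-`J01` ATC) are treated as
non-first-line and flagged in the reason trace. Categories are exhaustive
and mutually exclusive by construction; an exhaustive 72-cell grid test
checks the table against an independently coded oracle.

Justifications: comorbidity flags (diabetes, CHF, MI, COPD, asthma, CAD,
hypertension, cancer, CKD) from coded records in a lookback window
(default 365 days, per-condition overridable to mimic jurisdictions with
unlimited lookback), immunosuppressive medication (ATC `L04`, `H02AB`,
`L01`), interacting medication (`B01AA`), and Charlson score ≥ 3. The
Charlson weight table ships classic weights (renal disease and malignancy
2, the other tracked conditions 1, hypertension/CAD 0) because the
validated provincial variant is not public; the threshold 3 aligns with
the "moderate/severe" stratum onset. One condition registry serves both
the justification flags and the Charlson sum. OHIP diagnostic codes are
truncated ICD-9 and are matched against the ICD-9 stem lists.

## Trend analysis

Annual category counts are modelled with a Poisson GLM (log link, IRLS to
relative tolerance 1e-8, via statsmodels), offset `log(population)`,
calendar year categorical with the first year as reference — the
published comparison is final-vs-first year, and a `linear_year` option
exists for monotone-trend tests. With one observation per year the model
is saturated, so the categorical rate ratio equals the closed-form
two-cell MLE `(c₂/p₂)/(c₁/p₁)`; tests verify this to 1e-6 and Wald CI
coverage of ~95% by simulation. A zero count in any year makes the MLE
degenerate; the documented `add_half` continuity option adds 0.5 to all
counts and flags the result. Wald intervals are on the log scale,
matching standard GLM output. Rates are per 1000 cohort population;
direct age standardization takes a configurable reference weight table
(the real analysis's standard population is unpublished, so standardized
rates over real-shaped data are expected to match only approximately).
Annual cohort denominators are configuration (per province-year table);
when absent the per-province registry count is used for every year.

## Synthetic data generator

The generator emulates the joint structure of the two-province elderly
CAP cohort: ages truncated-normal (means 77.98/76.97, SDs 8.37/7.85,
floor 65), ~53–55% female, patient shares 27%/73% by province, ~2.3
episodes per patient over 2014–2018, visits per episode with means
~1.75/~1.35, prescribe probability 0.46/0.52, a dispensed-duration pmf
{7: 0.54, 10: 0.25, 5: 0.21}, comorbidity prevalences near the published
episode-level table (hypertension 0.78 dominating), and a category mix of
{adherent 0.015, clinically appropriate 0.68, effective-but-unnecessary
0.13, undertreatment 0.115, not recommended 0.06}. Sub-patterns follow
the published decompositions: excess prescribing is 93% duration-only;
subtherapeutic prescribing is dominated (79%) by low dose with excess
duration.

Generation works backwards from intended labels so ground truth is exact:

* Patients are drawn as **clean** (no justification of any kind) or
  **justified** strata, with stratum-conditional category mixes chosen so
  the marginal category mix equals the configured one for any feasible
  clean fraction (default 0.10). Clean patients are the only source of
  not-recommended prescribing; justified patients the only source of
  clinically-appropriate.
* An undertreatment draw for a CKD patient becomes a reclassified
  clinically-appropriate prescription — the reclassification route arises
  mechanically (≈ 1–2% of prescriptions, matching the published 2–4% of
  the clinically-appropriate category), at the cost of the marginal
  undertreatment share sitting slightly below its configured mass.
* Dose menus are whole units/day per agent, strictly inside or strictly
  outside the tolerance-widened bounds, so no generated dose can land on
  a boundary after rounding.
* Episodes of one patient are spaced ≥ ~400 days apart and justification
  records are emitted 30–280 days before each index date, so linkage
  windows and lookback windows can never leak across episodes.
* Each table draws from its own PCG64 stream derived from the master
  seed.

Deliberate edge cases — chronic visit runs (2%), post-episode admissions
(3%), decoy second/late dispensations (10%), long-term-care residents
(3%) — exercise the exclusion and first-dispensation rules;
`SimConfig.noiseless()` turns them all off. The generator re-derives
every intended category through the real decision table before returning
and hard-fails on any inconsistency.

What the generator does **not** emulate: billing-code dialect differences
beyond the configured lists, calendar trends in prescribing (category mix
is time-homogeneous, so fitted rate ratios on synthetic data are ≈ 1),
correlated comorbidity structure, income/rurality effects (independent
draws), refills, or inpatient dispensing. Passing round-trip tests
therefore demonstrates correctness of the pipeline's logic under the
stated data model, not robustness to real-world coding noise.

## Problem sizes and numerics

Round-trip acceptance runs use 10,000 patients (~22k episodes, ~11k
prescriptions), a size at which every binomial check has narrow intervals
while the full pipeline completes in seconds; Monte-Carlo CI calibration
uses 1000 replicates with expected counts of 100/150 per cell. Small-cell
suppression replaces counts < 6 (and any rate derived from them) with a
marker, applied at reporting only — classifier category counts always sum
to the linked-prescription count. Percentage differences are reported to
2 decimals; a zero starting rate yields a missing marker rather than a
division error.

## Known limitations

* The decision table grades only the first linked dispensation; therapy
  modifications after culture results are out of scope by design.
* CKD diagnosis is a proxy for renal function; with real data its low
  claims sensitivity shifts prescriptions from clinically-appropriate
  (reclassified) to undertreatment.
* Age standardization and provincial denominators are configuration; the
  package does not attempt to reconstruct unpublished standards.
* The published provincial rate ratios are not recomputable from the
  published standardized rates alone (unprinted denominators), so
  trend-model validation is by construction (closed form, simulation)
  rather than by matching printed ratios.
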