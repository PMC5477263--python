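# Methods

## Scope and data model

`mddpatterns` analyzes long-term pharmacotherapy patterns after first-line
antidepressant (AD) initiation in major depressive disorder, from three
tabular inputs: enrollment spans, pharmacy claims and medical claims (CSV
schemas in `mddpatterns.io`; claims data have no community-standard file
format). All dates are handled internally as integers on a day grid with
half-open intervals `[start, end)`, so a fill's supply ends on
`fill_date + days_supply` and all gap/window arithmetic is exact. Enrollment
`end_date` is inclusive on disk, converted at the boundary.

The enrollment table carries `birth_year`, `sex` and `region` alongside the
coverage interval: age at index is computed from birth year only, which is
the usual resolution of de-identified claims extracts.

## Patient selection

Criteria are evaluated in a fixed flowchart order (first AD fill exists; two
MDD-coded claims ≤ 183 days apart; an MDD claim within `[index − 30, index]`;
age ≥ 18 at index; gapless enrollment over `[index − 365, index + 730]`;
no different AD and no atypical antipsychotic (AAP) fill in
`[index, index + 30]`; no 295.xx claim ever). Inclusion is
order-insensitive; only the attrition attribution depends on the order. "Six
months" is fixed at 183 days and both endpoints of every window are
inclusive — claims-research conventions, exposed in `PipelineConfig`.
Continuous enrollment tolerates no gap by default (`enrollment_gap_tolerance_days`).
Whether the index-qualifying MDD claim must belong to the qualifying pair is
not determined by the design; any MDD-coded claim in the window qualifies
here.

## Exposure episodes and regimen identity

Fills map to coverage intervals; with stockpiling (default on) an early
refill's coverage is deferred until the current supply is exhausted, carrying
at most 90 leftover days. Coverage merges into exposure episodes while the
untreated gap is < 42 days; a gap ≥ 42 splits. Regimen identity is the set of
active-ingredient names, except that every AAP molecule maps to a single
interchangeable component: brand↔generic changes and AAP→AAP changes are
never regimen changes. Dose segments are kept per actual molecule (summing
concurrent fills of the same ingredient), because milligram comparisons
across different molecules are meaningless — in particular inside the pooled
AAP component.

## Change detection and precedence

Within a line (starting at the index date or at the previous change), the
engine scans candidates in event-date order:

* **add-on** — a component outside the regimen starting while the regimen is
  active: combination (second AD) or augmentation (AAP) for AD-monotherapy
  lines, switch/drop for multi-component lines; a component dropping while
  another continues is also switch/drop.
* **dose escalation** — a molecule's dose segment boundary with
  `new ≥ 1.5 x prior`, dated after day 21 of the line (titration window; it
  restarts with every new line). The reference is the immediately prior
  covered segment; a config flag compares to the line's starting dose
  instead. A dose decrease is never an event, but it does update the
  reference, so a later rebound ≥ 1.5x the lowered dose is an escalation. A
  molecule re-emerging from a bridged gap *at the start of a line* defines
  that line's baseline dose rather than an event.
* **regimen end** — when all components' supply has ended: a different
  regimen starting within ≤ 42 days (inclusive) is a switch, dated at the new
  regimen's start; otherwise, once 42 untreated days accumulate (or would
  accumulate before the study end), a discontinuation dated at the supply
  end, followed by a resumption at the next initiation if one exists.

Same-day ties break add-on > escalation > regimen-end events. The
42-days-exactly corner is resolved as: a *different* regimen at gap 42 is a
switch (the switch definition supersedes the discontinuation it follows);
the *same* regimen can only re-start at gap ≥ 42 (shorter gaps are bridged)
and is a discontinuation followed by resumption.

Line duration is `event_date − line_start`, except for a switch, where it is
the prior regimen's supply end minus the line start (the untreated gap is not
treatment time); a line is adequate at ≥ 42 days. The interval between a
discontinuation and a resumption is recorded as a line whose duration is the
gap length, hence always adequate. Up to four changes are followed; with no
further change a line terminates as persistence, or as "remained untreated"
after a final discontinuation. A discontinuation whose 42-day gap does not
complete before the study end is not an event (the patient is persistent from
the last regimen onward).

### Verification oracle

`day_grid_oracle` re-implements the definitions literally on per-day arrays:
daily dose vectors per molecule, bridged activity runs, day-by-day scanning
for add-ons, dose changes and gap lengths. It shares no interval algebra with
the engine and is held equal to it, event for event, on every synthetic
fixture and on thousands of randomized fill histories (property tests and
the acceptance script).

## Patterns, cohorts, frequencies

The first change defines the cohort; pattern strings join change tokens with
`" → "` plus a terminal `Persistence`/`Remained Untreated` token when fewer
than four changes were observed (none after a fourth change). The analysis
sub-sample requires every observed line adequate. Frequency tables report
counts and percentages of the sub-sample total, rounded **half-up** to one
decimal (this reproduces every printed percentage of the published cohort
table from its printed counts); cohorts under 5% of the sub-sample (strict
inequality) are flagged as not analyzed for HCRU/costs. Time to
discontinuation is `(event − index)/7` weeks, summarized by the cohort
median, measured from the index date.

## HCRU and costs

Days with medical visits = inpatient length of stay (window-truncated) plus,
per non-inpatient setting, distinct calendar days with ≥ 1 claim. The default
total sums over settings, so one calendar day with an ER and an outpatient
claim contributes two; a `distinct_day_mode` flag counts it once instead (the
published definition reads as a sum over settings, but the intent is not
certain, so both are implemented). A day unit is mental-health-related if any
of its claims carries an ICD-9 code with integer prefix 290–319.

Costs are paid amounts inflated to 2014 USD by a medical-CPI table
(`amount x cpi[2014]/cpi[year]`). The CPI table is user-supplied
configuration; the shipped table is **illustrative** (a smooth ~4%/year
trend), not official index values. Total cost = medical + pharmacy exactly;
MDD-related pharmacy cost is the AD + AAP class subtotal; mental-health
medical cost is the 290–319-coded subtotal. Follow-up for PPPY runs from the
index date to the end of continuous enrollment, with a 365.25-day year and a
hard 730-day minimum. Group summaries annualize per patient before averaging
and are checked against per-patient brute-force recomputation.

The Charlson comorbidity index uses the Quan ICD-9-CM adaptation: unit
weights for eight conditions plus `max(mild liver, 3x moderate/severe
liver)`, `max(mild diabetes, 2x chronic diabetes)`, `2x hemiplegia`,
`2x renal`, `max(2x malignancy, 6x metastatic solid tumor)` and `6x AIDS`.
Condition flags come from the standard published prefix lists.

## Synthetic data

The generator scripts each patient's trajectory (`TrajectoryScript`): an
ordered list of at most four change steps with day offsets and parameters,
validated against the change definitions (escalation after day 21 and ≥ 1.5x;
resumption gaps ≥ 42 days; switch gaps ≤ 42 days; add-ons only on
AD-monotherapy lines). Compilation emits back-to-back 30-day fills whose
supply ends exactly where the script demands, so the intended events hold by
construction and the ground-truth table (cohort, pattern, change dates,
adequacy) is exact. Visits are Poisson per setting, costs lognormal per
setting and drug class, diagnoses mental-health-coded with a configured
probability (avoiding MDD/schizophrenia codes so negative controls stay
valid). Calendar time spans 2003–2014 to exercise the CPI adjustment. One
negative-control script exists per selection criterion, violating exactly
that criterion.

The calibrated scenario draws cohorts from the published sub-sample
proportions (49.1 / 37.4 / 6.6 / 3.5 / 2.8 / 0.7%), first-line
time-to-discontinuation from a lognormal with a 23-week median (σ = 0.5,
capped at 600 days — far above the median), an SSRI-dominated index-class
mix, 61.1% female, and 18–79 ages; all scripted lines are adequate, so the
sub-sample equals the population and observed shares estimate the configured
mix directly. Other timing parameters (gaps 43–120 days, line durations
43–200 days, enrollment lead 365–500 days, follow-up 760–1400 days extended
to fit the scripted horizon) are fixed, field-plausible choices. Problem
sizes are 600 scripted patients in the test suite, 800 in the acceptance
script and 1000 randomized histories for the oracle cross-check — large
enough that binomial error on cohort shares is a few percentage points.

What passing tests show: the engine applies the stated definitions exactly
(boundaries day-for-day), recovers scripted trajectories perfectly, and the
aggregation identities hold. What they do not show: behaviour on real claims
(irregular refill timing, partial adherence, multi-payer churn, coding noise),
realistic cost magnitudes (the published dollar values derive from
proprietary data and are out of scope as exact targets), or therapeutic
appropriateness of doses — dose-range adequacy and lithium/thyroid
augmentation are deliberately not modelled.

## Numerical choices

Dose comparisons use a 1e-9 absolute tolerance; equal-dose adjacent segments
merge. Ties in fill ordering resolve by (date, ingredient). Percentages round
half-up via decimal arithmetic, never float `round`. Empty inputs yield empty
outputs with explicit warnings rather than errors; a follow-up below the
study minimum raises.

## Known limitations

* The engine assumes fills after the index are the complete pharmacotherapy
  record; pre-index AAP supply spilling over the index date would join the
  first-line regimen.
* The literal reading of "days with medical visits" (sum over settings)
  inflates totals relative to distinct-day counting when same-day
  multi-setting care is common.
* The Quan prefix lists are at 3–5-digit granularity; exotic five-digit
  exceptions inside a listed three-digit family are not distinguished.
* Scripted trajectories exercise the definitions, not the messiness of real
  refill behaviour; the randomized-history oracle check covers irregular
  timing but still with simple dose structures.
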