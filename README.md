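# mddpatterns

Line-of-therapy treatment patterns and per-patient-per-year (PPPY) healthcare
burden for major depressive disorder (MDD), derived from administrative
claims.

Retrospective claims studies of antidepressant use need three things that are
easy to get subtly wrong: a patient-selection flowchart (diagnosis codes,
enrollment windows, monotherapy rules), a *line-of-therapy engine* that turns
pharmacy fills into treatment-change events, and PPPY normalization of
utilization and costs. `mddpatterns` implements all three as a tested,
configurable pipeline, together with a synthetic-claims generator that scripts
patient trajectories with known ground truth — so the whole analysis can be
validated end to end without access to proprietary claims data.

## The model

Patients enter at the **index date** — their first-ever antidepressant (AD)
fill — if they have two MDD-coded claims (ICD-9 296.2x/296.3x) within six
months, an MDD claim at most 30 days before the index fill, are ≥18, are
continuously enrolled 12 months before and 24 months after index, start as AD
monotherapy (no second AD/atypical antipsychotic within 30 days), and never
carry a schizophrenia code (295.xx).

From the index date, fills are merged into per-ingredient **exposure
episodes** (a supply gap ≥ 42 days splits an episode) and the engine detects
the first qualifying change of each line of therapy:

| change | definition (defaults) |
|---|---|
| discontinuation | ≥ 42 consecutive days without supply of the line's regimen |
| dose escalation | daily dose (strength x quantity / days supply) ≥ 1.5x the prior dose, after day 21 of the line |
| switch | a different regimen starts within 42 days of the prior regimen's supply end |
| combination | a second AD overlaps the active AD |
| augmentation | an atypical antipsychotic (AAP) overlaps the active AD |
| switch/drop | any regimen change within a multi-drug line (dropping one component counts) |
| resumption | re-initiation after a discontinuation gap |

Regimens are compared at active-ingredient level: brand↔generic is not a
switch, and all AAP molecules are interchangeable. The first change defines
the patient's **cohort** (persistence if no change ever occurs); changes are
followed through the fourth line. The analysis sub-sample keeps patients with
≥ 42 days of treatment before every observed change; cohorts under 5% of the
sub-sample are flagged as not analyzed. Costs are CPI-adjusted to 2014 USD
and, like days-with-medical-visits, reported PPPY
(value x 365.25 / follow-up days).

A brute-force day-grid simulator (`day_grid_oracle`) re-derives every event
calendar-day by calendar-day and is held equal to the interval engine on
thousands of randomized fill histories.

## Worked example

```python
from mddpatterns import PipelineConfig, run_pipeline

bundle = run_pipeline(PipelineConfig(), "out/", simulate_n=600, seed=11)
freq = bundle["frequency"]
print(freq[freq.row_type == "cohort"][["label", "count", "percent"]].to_string(index=False))
print("median weeks to discontinuation:",
      round(bundle["weeks_to_discontinuation"].median(), 1))
```

prints

```
          label  count  percent
Discontinuation    281     46.8
     Escalation    239     39.8
         Switch     40      6.7
    Persistence     20      3.3
    Combination     18      3.0
   Augmentation      2      0.3
median weeks to discontinuation: 23.4
```

i.e. on a 600-patient simulated population, discontinuation is the most
common first treatment change (46.8% of the analysis sub-sample), followed by
dose escalation and switch, and half of the discontinuation cohort stops
first-line therapy within about 23 weeks — the engine-derived labels match
the scripted ground truth for every patient. `out/` receives the attrition,
events, pattern, frequency, HCRU/cost and baseline tables plus a
`manifest.json` recording the config hash and seed.

The same pipeline runs from the shell:

```bash
mddpatterns simulate --seed 7 --n-patients 500 --out data/
mddpatterns select --enrollment data/enrollment.csv --pharmacy data/pharmacy.csv \
    --medical data/medical.csv --out data/step
mddpatterns classify --selection data/step_selection.csv --pharmacy data/pharmacy.csv \
    --out data/step
mddpatterns report --patterns data/step_patterns.csv --out data/step
```

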