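# mpr-monitor

Medication-adherence analytics from pharmacy prescription-fulfillment
records: running Medication Possession Ratio (MPR), refill-gap
detection, current non-adherence flags, and logistic one-year
non-adherence prediction, with per-medication clinician-style
assessments.

It is aimed at health-informatics developers and researchers who have
flat-file dispensing histories (one row per fill: patient, medication,
fill date, days of supply) and want reproducible adherence indicators
at the point of care or in retrospective analyses.

## The measures

For one medication, with day 0 the first fill and *t* days elapsed,

```
MPR(t) = (total days of supply dispensed on days ≤ t) / t
```

the running MPR. It is uncapped by default (early refills push it above
1); an opt-in cap at 1 gives the proportion-of-days-covered (PDC)
convention. Three checks combine into one flag per medication:

1. **Gap check (RED)** — build the possession timeline (unused supply
   from early refills is banked by default) and flag any maximal
   uncovered run *strictly* longer than 30 days, at any time in the
   record including trailing time to the observation date. A
   `cumulative` mode (elapsed days minus total supply at end of record)
   is also available; the two agree on single-fill histories.
2. **Current-MPR check (RED)** — MPR strictly below 0.8 at the latest
   observed day.
3. **One-year forecast (YELLOW/GREEN)** — for medications that pass the
   gap check, map to a configured drug class (antihyperlipidemics,
   antihypertensives, oral hypoglycemics in the shipped example), and
   have ≥ 60 observed days, a two-covariate logistic model

   ```
   P(poor 1-year adherence) = 1 / (1 + exp(−(β₀ + β_age·age + β_mpr·MPR(d))))
   ```

   is applied at the latest available prediction day d ∈ {60, 90, 120}.
   Poor forecasts flag YELLOW; acceptable ones GREEN. A full observed
   year with MPR(365) ≥ 0.8 is GREEN outright and supersedes any
   forecast. Medications with no current problem and no forecast basis
   get NONE. Precedence is RED > YELLOW > GREEN > NONE.

Coefficients are external configuration (JSON), one model per (drug
class, prediction day). The packaged `data/example_models.json` holds
**synthetic placeholder values**; substitute coefficients estimated
from real claims data for any clinical use.

## Worked example

Generate a small synthetic cohort (seeded, deterministic) and assess it
with the packaged example configuration:

```
$ mpr-monitor simulate --n 6 --mix "perfect=0.5,discontinue=0.3,fixed_delay=0.2" \
      --seed 7 --horizon 200 --out demo/
wrote demo/cohort.csv and demo/truth.csv (as-of date 2020-07-19)

$ mpr-monitor report --fills demo/cohort.csv --classes example_classes.tsv \
      --models example_models.json --as-of 2020-07-19 --format csv --out demo/
wrote demo/report.csv (6 assessment(s))
```

`report.csv` then contains:

```
patient_id,medication_id,medication_name,status,reasons,current_mpr,first_fill_date,last_fill_date,n_gaps,longest_gap_days,prediction_day,probability_poor
P0,cyclobenzaprine,Cyclobenzaprine,RED,GAP_OVER_30;CURRENT_MPR_BELOW_0_8,0.150000,2020-01-01,2020-01-01,1,170,,
P1,cyclobenzaprine,Cyclobenzaprine,RED,GAP_OVER_30;CURRENT_MPR_BELOW_0_8,0.150000,2020-01-01,2020-01-01,1,170,,
P2,furosemide,Furosemide,RED,CURRENT_MPR_BELOW_0_8,0.750000,2020-01-01,2020-06-09,5,10,,
P3,metformin,Metformin,GREEN,PREDICTED_OK_1Y,1.050000,2020-01-01,2020-06-29,0,0,120,0.055410
P4,ramipril,Ramipril,GREEN,PREDICTED_OK_1Y,1.050000,2020-01-01,2020-06-29,0,0,120,0.031907
P5,simvastatin,Simvastatin,GREEN,PREDICTED_OK_1Y,1.050000,2020-01-01,2020-06-29,0,0,120,0.055357
```

Reading the rows: the two discontinuers stopped after one 30-day fill,
leaving a 170-day gap and MPR 30/200 = 0.15 — current non-adherence,
RED, and no forecast is attempted. The fixed-delay patient refills 10
days late each cycle: every gap is 10 days (no alert) but the current
MPR is 150/200 = 0.75 < 0.8, so the medication is RED on the MPR check
alone. The perfect adherers hold MPR 210/200 = 1.05; with no current
problem and a configured class, the 120-day model forecasts a low
probability of poor 1-year adherence (≈ 0.03–0.06 under the placeholder
coefficients), hence GREEN. `truth.csv` carries the generator's ground
truth (pattern, true gaps, expected MPR) for validation.

The same pipeline is available as a library (`parse_cohort`,
`classify_medication`, `assess_patient`, `export_plot_data`), with JSON
and static-HTML report formats, and all thresholds (30-day gap, 0.8
MPR, 365-day year, cap-at-one, gap mode) exposed as options.

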