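# Methods

## Data model and conventions

Input is one row per dispensing event: patient, medication code and
display name, ISO fill date, and days of supply (the days one fill
covers at the prescribed daily dose; a dose-quantity pair is not
supported — the file must carry days directly). Rows are grouped into
one history per (patient, medication); same-day duplicate rows are
summed, since partial fills occur in claims data. Distinct medication
codes are distinct histories even when they share an ingredient.

All arithmetic uses integer day offsets from each medication's first
fill (day 0) and half-open intervals [start, end), which make lengths
unambiguous and remove timezone/clock concerns. The observation bound
`as_of` defaults to the latest fill date in the file and can be
overridden; nothing reads the wall clock, so identical inputs always
give identical output.

## Possession timeline

With carryover (the default), a supply "bank" is tracked: a refill
before run-out extends coverage forward, so coverage runs until the
cumulative dispensed supply is exhausted. Without carryover each fill
covers exactly its own window and overlaps merge without banking.
Coverage is truncated at the horizon. Correctness is checked against a
literal day-by-day simulation (a daily supply counter, topped up on
fill days) on randomized histories; the two agree exactly, not within
tolerance, because both are integer arithmetic.

## Running MPR

MPR(t) = dispensed supply on days ≤ t, divided by t. Choices made
where conventions differ:

* **Fill-day inclusion** — a fill on day d counts from evaluation day d
  onward: the patient possesses medication on the day it is dispensed.
* **Undefined at day 0** — the elapsed-days denominator is zero; series
  start at day 1.
* **Uncapped by default** — early refills legitimately push MPR above
  1. The cap-at-one option gives the PDC-style variant. One
  consequence worth noting: under perfect adherence the uncapped MPR is
  ≥ 1 at every day and touches 1 only in the capped variant, because
  the refill lands exactly on the run-out boundary and is counted from
  that day.
* **Between fills the curve is strictly decreasing** (supply constant,
  denominator growing) and jumps up at each fill — the familiar
  sawtooth. Dense series sample every day; sparse series keep only
  breakpoints and agree with dense at shared days.

## Gap detection

Default (`interval`) mode reports every maximal uncovered run in
[0, horizon), including trailing time to the observation date, and
alerts when a run is strictly longer than 30 days (a 30-day gap does
not alert; 31 does). The alternative `cumulative` mode subtracts total
dispensed supply from elapsed time at the end of the record and reports
any positive shortfall as a single trailing gap. The two coincide on
single-fill histories; on multi-fill histories an interior lapse that
is later "made up" alerts only in interval mode. Interval mode is the
default because gaps are meaningful whenever they occur, not only at
the end of the record; the cumulative variant is kept because it is the
natural single-subtraction reading and costs nothing to expose.

## Current-MPR check

MPR at the latest observed day, flagged iff strictly below 0.8 — the
conventional adherence cut-point. Exactly 0.8 passes.

## One-year forecast

A logistic model with two covariates — age at first fill (years, as a
real number) and the uncapped MPR at the prediction day — emits the
probability of poor adherence, defined as 1-year MPR < 0.8. The
prediction day is the latest of {60, 90, 120} not exceeding the
observed span; once 120 days are observed the 120-day model is used
regardless of how much later the record extends, so the forecast is
always anchored to early fill behavior. The binary call uses a
configurable threshold, default 0.5, inclusive (p = threshold predicts
poor). The logistic is evaluated in the numerically stable two-branch
form, so extreme linear predictors saturate without overflowing.

Models are external JSON configuration keyed by (drug class, prediction
day); the drug-class map is a two-column TSV matched case-insensitively
on code or name. Duplicate keys with conflicting classes and duplicate
(class, day) records are fatal configuration errors. The packaged
example coefficients are synthetic placeholders chosen only for
plausible orientation (higher early MPR and, mildly, higher age lower
the risk in these chronic classes); they carry no empirical content and
must be replaced with estimates from real dispensing data for any
substantive use.

## Status resolution

RED > YELLOW > GREEN > NONE, resolved in order:

1. Gap alert or current MPR < 0.8 → RED. Both checks run on every
   medication regardless of class; a RED medication never carries a
   forecast (its MPR series and gaps are still exported for plotting).
2. Otherwise, if ≥ 365 days are observed and MPR at day 365 ≥ 0.8 →
   GREEN on the observed outcome, which supersedes any forecast. "One
   year" is fixed at 365 days for determinism.
3. Otherwise a forecast is attempted (mapped class, span ≥ 60, model
   and age available): poor → YELLOW, acceptable → GREEN.
4. Otherwise NONE, with a machine-readable reason (span too short, or
   no model/class/age).

Patient listings order mapped classes first (alphabetical), then
unmapped medications, alphabetically within each group — a repo
convention, as is the static single-file HTML report (no interactive
plotting).

## Synthetic cohorts

The generator emulates refill behavior, not claims-database mechanics:
five patterns (perfect, fixed delay, geometric random delay,
discontinuation, early refill) over a single medication per patient
with constant days-supply. Defaults — 30-day supply, 365-day horizon,
10-day delays, discontinuation after day 30, 5-day early-refill lead,
ages N(55, 12²) truncated to [18, 95] — reflect typical chronic-
medication dispensing. Geometric delays were chosen as a one-parameter
memoryless model of refill procrastination. Pattern counts are
allocated by largest remainder, so proportions are hit exactly; all
randomness flows from one explicit seed through a named generator, and
identical seeds give byte-identical CSVs.

Gap ground truth is tracked analytically during construction (delays
and run-outs are known by design), independently of the analyzer's
interval arithmetic, which is what makes generator/analyzer agreement a
meaningful check. What passing on synthetic data does **not** show:
robustness to real-world quirks such as fill reversals, 90-day
mail-order mixes, therapy switches, or overlapping prescriptions of one
ingredient at different strengths — none of which are emulated.

## Verification sizes and numerical notes

The test suite and acceptance script use 1,000 randomized histories
(1–8 fills, supplies 1–90 days, horizons to ~18 months) for the
oracle-equivalence check and a 100-patient 50/50 perfect/discontinuer
cohort for recovery metrics; both run in seconds. Timeline, gap and
MPR comparisons are exact integer/rational checks; logistic values are
compared to independent scalar evaluation at 1e-12 relative tolerance.
Degenerate inputs are defined, not guessed at: empty files parse to
empty results, a history whose observation span is zero days yields
NONE (no check is computable), and every history always yields exactly
one assessment.
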