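"""Seeded synthetic fulfillment histories with known ground truth.

Real pharmacy-claims data cannot ship with the package, so tests and
demos run on generated cohorts whose adherence behavior is constructed,
not inferred.  Five refill behaviors are modelled:

* ``perfect`` — refill exactly at run-out; MPR stays at 1.
* ``fixed_delay`` — refill a fixed number of days after run-out.
* ``random_delay`` — delays drawn from a geometric distribution with a
  given mean (memoryless procrastination), seeded.
* ``discontinue`` — refills stop at a given day; the record then runs
  uncovered to the horizon.
* ``early_refill`` — refill a fixed number of days before run-out;
  unused supply banks up and MPR exceeds 1.

The gap structure of each history is tracked analytically during
construction (delays and run-outs are known by design), giving ground
truth that is independent of the interval arithmetic in the analyzer.
All randomness flows from one explicit seed through a named generator.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .records import FulfillmentRecord, MedicationHistory, Patient, write_fulfillments

PATTERNS = ("perfect", "fixed_delay", "random_delay", "discontinue", "early_refill")
DEFAULT_START_DATE = date(2020, 1, 1)

# name -> (medication_id, drug_class or None); classes match the packaged example map
MEDICATIONS = {
    "Simvastatin": ("simvastatin", "antihyperlipidemics"),
    "Ramipril": ("ramipril", "antihypertensives"),
    "Furosemide": ("furosemide", "antihypertensives"),
    "Metformin": ("metformin", "oral_hypoglycemics"),
    "Cyclobenzaprine": ("cyclobenzaprine", None),
}


@dataclass(frozen=True)
class BehaviorSpec:
    """Parameters of one synthetic refill behavior.

    ``delay_days`` is the fixed delay after run-out (fixed_delay) or the
    mean delay (random_delay); ``discontinue_day`` is the day after
    which no further fills occur; ``refill_lead`` is how many days
    before run-out an early refill happens.
    """

    pattern: str
    days_supply: int = 30
    horizon_days: int = 365
    delay_days: int = 0
    discontinue_day: int = 0
    refill_lead: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}; expected one of {PATTERNS}")
        if self.horizon_days < 1:
            raise ValueError("horizon_days must be >= 1")
        if self.days_supply < 1:
            raise ValueError("days_supply must be >= 1")
        if min(self.delay_days, self.discontinue_day, self.refill_lead) < 0:
            raise ValueError("pattern parameters must be nonnegative")
        if self.pattern == "early_refill" and self.refill_lead >= self.days_supply:
            raise ValueError("refill_lead must be smaller than days_supply")


@dataclass
class GroundTruth:
    """Analytic truth for one generated history."""

    pattern: str
    fill_days: list[int]
    supplies: list[int]
    horizon: int
    gap_intervals: list[tuple[int, int]] = field(default_factory=list)
    gap_threshold_days: int = 30

    @property
    def gap_lengths(self) -> list[int]:
        return [e - s for s, e in self.gap_intervals]

    @property
    def has_gap_alert(self) -> bool:
        return any(length > self.gap_threshold_days for length in self.gap_lengths)

    @property
    def total_supply(self) -> int:
        return sum(self.supplies)

    def mpr_at(self, day: int) -> float:
        """Closed-form running MPR: dispensed supply over elapsed days."""
        if day < 1:
            raise ValueError("MPR undefined before day 1")
        return sum(s for d, s in zip(self.fill_days, self.supplies) if d <= day) / day

    @property
    def current_mpr(self) -> float:
        return self.mpr_at(self.horizon)


def _fill_schedule(spec: BehaviorSpec, rng: np.random.Generator):
    """Construct fill days and the gap intervals implied by the pattern."""
    s, horizon = spec.days_supply, spec.horizon_days
    fill_days: list[int] = []
    gaps: list[tuple[int, int]] = []
    day = 0
    runout = 0  # exclusive end of coverage given fills so far
    while day < horizon:
        if spec.pattern == "discontinue" and fill_days and day >= spec.discontinue_day:
            break
        if day > runout:  # coverage lapsed before this fill
            gaps.append((runout, day))
        fill_days.append(day)
        runout = max(runout, day) + s if day >= runout else runout + s
        if spec.pattern == "perfect" or spec.pattern == "discontinue":
            day = runout
        elif spec.pattern == "fixed_delay":
            day = runout + spec.delay_days
        elif spec.pattern == "random_delay":
            mean = spec.delay_days
            # geometric on {0,1,2,...} with the requested mean
            delay = 0 if mean == 0 else int(rng.geometric(1.0 / (mean + 1.0)) - 1)
            day = runout + delay
        elif spec.pattern == "early_refill":
            day = max(runout - spec.refill_lead, day + 1)
    if runout < horizon:
        gaps.append((runout, horizon))
    return fill_days, gaps


def generate_history(
    spec: BehaviorSpec,
    patient_id: str = "P000",
    medication_id: str = "metformin",
    medication_name: str = "Metformin",
    start_date: date = DEFAULT_START_DATE,
) -> tuple[MedicationHistory, GroundTruth]:
    """One synthetic medication history plus its analytic ground truth.

    Identical spec (including seed) always yields identical output.
    """
    rng = np.random.default_rng(spec.seed)
    fill_days, gaps = _fill_schedule(spec, rng)
    fills = [
        FulfillmentRecord(
            patient_id, medication_id, medication_name,
            start_date + timedelta(days=d), spec.days_supply,
        )
        for d in fill_days
    ]
    history = MedicationHistory(
        patient_id, medication_id, medication_name, fills,
        as_of_date=start_date + timedelta(days=spec.horizon_days),
    )
    truth = GroundTruth(
        pattern=spec.pattern,
        fill_days=fill_days,
        supplies=[spec.days_supply] * len(fill_days),
        horizon=spec.horizon_days,
        gap_intervals=gaps,
    )
    return history, truth


@dataclass
class CohortResult:
    """Generated cohort: fulfillment CSV text, truth table, observation date."""

    fills_csv: str
    truth: pd.DataFrame
    as_of_date: date

    def truth_csv(self) -> str:
        buf = io.StringIO()
        self.truth.to_csv(buf, index=False, lineterminator="\n")
        return buf.getvalue()


def _allocate(n: int, proportions: dict[str, float]) -> list[str]:
    """Deterministic largest-remainder allocation of n items to keys."""
    total = sum(proportions.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"proportions must sum to 1 (got {total})")
    keys = sorted(proportions)
    counts = {k: int(n * proportions[k]) for k in keys}
    remainders = sorted(
        keys, key=lambda k: (-(n * proportions[k] - counts[k]), k)
    )
    for k in remainders[: n - sum(counts.values())]:
        counts[k] += 1
    out: list[str] = []
    for k in keys:
        out.extend([k] * counts[k])
    return out


def generate_cohort(
    n_patients: int,
    behavior_mix: dict[str, float],
    classes_mix: dict[str, float] | None = None,
    age_distribution: tuple[float, float] = (55.0, 12.0),
    seed: int = 0,
    days_supply: int = 30,
    horizon_days: int = 365,
    delay_days: int = 10,
    discontinue_day: int = 30,
    refill_lead: int = 5,
) -> CohortResult:
    """A seeded cohort of one-medication patients with known behaviors.

    ``behavior_mix`` maps pattern name to proportion (must sum to 1);
    counts are allocated deterministically by largest remainder, so a
    50/50 mix of 100 patients is exactly 50/50.  ``classes_mix`` maps
    medication display names (from the built-in formulary) to
    proportions; default is an even mix over the formulary.  Ages are
    drawn from a normal distribution (mean, sd) truncated to [18, 95].
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    for p in behavior_mix:
        if p not in PATTERNS:
            raise ValueError(f"unknown pattern {p!r} in behavior_mix")
    if classes_mix is None:
        classes_mix = {name: 1.0 / len(MEDICATIONS) for name in MEDICATIONS}
    for m in classes_mix:
        if m not in MEDICATIONS:
            raise ValueError(f"unknown medication {m!r}; formulary: {sorted(MEDICATIONS)}")

    patterns = _allocate(n_patients, behavior_mix)
    meds = _allocate(n_patients, classes_mix)
    rng = np.random.default_rng(seed)
    ages = np.clip(rng.normal(*age_distribution, size=n_patients), 18.0, 95.0).round(1)

    width = len(str(n_patients - 1))
    histories: list[MedicationHistory] = []
    patients: dict[str, Patient] = {}
    truth_rows = []
    for i in range(n_patients):
        pid = f"P{i:0{width}d}"
        med_name = meds[i]
        med_id, drug_class = MEDICATIONS[med_name]
        spec = BehaviorSpec(
            pattern=patterns[i],
            days_supply=days_supply,
            horizon_days=horizon_days,
            delay_days=delay_days,
            discontinue_day=discontinue_day,
            refill_lead=refill_lead,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        history, truth = generate_history(spec, pid, med_id, med_name)
        histories.append(history)
        patients[pid] = Patient(pid, float(ages[i]))
        truth_rows.append(
            {
                "patient_id": pid,
                "medication_id": med_id,
                "medication_name": med_name,
                "drug_class": drug_class or "",
                "pattern": patterns[i],
                "age_at_first_fill": float(ages[i]),
                "n_fills": len(truth.fill_days),
                "n_gaps": len(truth.gap_intervals),
                "longest_gap_days": max(truth.gap_lengths, default=0),
                "expected_gap_alert": truth.has_gap_alert,
                "expected_current_mpr": truth.current_mpr,
            }
        )

    fills_csv = write_fulfillments(histories, patients)
    truth_df = pd.DataFrame(truth_rows)
    as_of = DEFAULT_START_DATE + timedelta(days=horizon_days)
    return CohortResult(fills_csv, truth_df, as_of)
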