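"""Core record types and flat-file I/O for prescription fulfillment data.

The input dialect is a UTF-8 CSV with a header row and columns
``patient_id, medication_id, medication_name, fill_date, days_supply``
plus an optional ``age_at_first_fill``.  Dates are ISO 8601
(YYYY-MM-DD); ``days_supply`` is the number of days one dispensed fill
covers at the prescribed daily dose.  All downstream arithmetic works on
integer day offsets from each medication's first fill (day 0).
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass
from datetime import date
from typing import Iterable, TextIO

import pandas as pd

REQUIRED_COLUMNS = (
    "patient_id",
    "medication_id",
    "medication_name",
    "fill_date",
    "days_supply",
)
AGE_COLUMN = "age_at_first_fill"


class FormatError(ValueError):
    """The file as a whole is malformed (e.g. a required column is missing)."""


class RowError(ValueError):
    """A single data row is invalid; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class FulfillmentRecord:
    """One pharmacy dispensing event.

    ``days_supply`` is the days of medication dispensed by this fill —
    the per-fill quantity in the MPR numerator.
    """

    patient_id: str
    medication_id: str
    medication_name: str
    fill_date: date
    days_supply: int

    def __post_init__(self):
        if self.days_supply < 1:
            raise ValueError(f"days_supply must be >= 1, got {self.days_supply}")
        if not isinstance(self.fill_date, date):
            raise TypeError("fill_date must be a datetime.date")


@dataclass
class MedicationHistory:
    """Ordered fills of one medication for one patient plus an observation bound.

    The first fill defines day 0; ``as_of_date`` is the (inclusive) last
    date of observation and must not precede the last fill.  ``horizon``
    is the exclusive integer-day end of observation: the number of days
    elapsed since the first fill.
    """

    patient_id: str
    medication_id: str
    medication_name: str
    fills: list[FulfillmentRecord]
    as_of_date: date

    def __post_init__(self):
        if not self.fills:
            raise ValueError("a medication history requires at least one fill")
        self.fills = sorted(self.fills, key=lambda f: f.fill_date)
        for f in self.fills:
            if f.patient_id != self.patient_id or f.medication_id != self.medication_id:
                raise ValueError("all fills must share patient_id and medication_id")
        if self.as_of_date < self.fills[-1].fill_date:
            raise ValueError("as_of_date must not precede the last fill date")

    @property
    def first_fill_date(self) -> date:
        return self.fills[0].fill_date

    @property
    def last_fill_date(self) -> date:
        return self.fills[-1].fill_date

    @property
    def horizon(self) -> int:
        """Days elapsed between first fill and as_of_date."""
        return (self.as_of_date - self.first_fill_date).days

    def day_of(self, d: date) -> int:
        return (d - self.first_fill_date).days

    @property
    def fill_days(self) -> list[int]:
        """Integer day offsets of each fill relative to the first."""
        origin = self.first_fill_date
        return [(f.fill_date - origin).days for f in self.fills]

    @property
    def fill_supplies(self) -> list[int]:
        return [f.days_supply for f in self.fills]

    @property
    def total_supply(self) -> int:
        return sum(f.days_supply for f in self.fills)


@dataclass(frozen=True)
class Patient:
    """Demographics needed by the prediction model: age at first fill, in years."""

    patient_id: str
    age_at_first_fill: float | None = None

    def __post_init__(self):
        if self.age_at_first_fill is not None and self.age_at_first_fill < 0:
            raise ValueError("age_at_first_fill must be >= 0")


def _parse_rows(source: TextIO | str):
    """Yield validated row dicts with 1-based line numbers."""
    if isinstance(source, str):
        source = io.StringIO(source)
    reader = csv.DictReader(source)
    if reader.fieldnames is None:
        return  # empty file: no header, no rows
    missing = [c for c in REQUIRED_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    has_age = AGE_COLUMN in reader.fieldnames
    for row in reader:
        line = reader.line_num
        try:
            fill_date = date.fromisoformat(row["fill_date"].strip())
        except (ValueError, AttributeError):
            raise RowError(line, f"unparseable fill_date {row.get('fill_date')!r}")
        try:
            days_supply = int(str(row["days_supply"]).strip())
        except (ValueError, TypeError):
            raise RowError(line, f"unparseable days_supply {row.get('days_supply')!r}")
        if days_supply < 1:
            raise RowError(line, f"days_supply must be >= 1, got {days_supply}")
        age = None
        if has_age and row.get(AGE_COLUMN) not in (None, ""):
            try:
                age = float(row[AGE_COLUMN])
            except ValueError:
                raise RowError(line, f"unparseable {AGE_COLUMN} {row[AGE_COLUMN]!r}")
            if age < 0 or not math.isfinite(age):
                raise RowError(line, f"{AGE_COLUMN} must be a finite nonnegative number")
        yield {
            "patient_id": str(row["patient_id"]).strip(),
            "medication_id": str(row["medication_id"]).strip(),
            "medication_name": str(row["medication_name"]).strip(),
            "fill_date": fill_date,
            "days_supply": days_supply,
            "age": age,
        }


def parse_cohort(
    source: TextIO | str, as_of_date: date | None = None
) -> tuple[list[MedicationHistory], dict[str, Patient]]:
    """Parse a fulfillment CSV into histories grouped by (patient, medication).

    Duplicate (patient, medication, date) rows have their days_supply
    summed — partial fills on the same day are one dispensing event.
    ``as_of_date`` defaults to the maximum fill date in the file; it may
    not precede any history's last fill.

    Returns the histories plus a patient table built from the optional
    ``age_at_first_fill`` column (patients without an age get None).
    """
    groups: dict[tuple[str, str], dict] = {}
    ages: dict[str, float] = {}
    max_date: date | None = None
    for row in _parse_rows(source):
        key = (row["patient_id"], row["medication_id"])
        g = groups.setdefault(key, {"name": row["medication_name"], "fills": {}})
        g["fills"][row["fill_date"]] = g["fills"].get(row["fill_date"], 0) + row["days_supply"]
        if row["age"] is not None:
            ages.setdefault(row["patient_id"], row["age"])
        if max_date is None or row["fill_date"] > max_date:
            max_date = row["fill_date"]

    histories: list[MedicationHistory] = []
    for (pid, mid), g in groups.items():
        fills = [
            FulfillmentRecord(pid, mid, g["name"], d, s)
            for d, s in sorted(g["fills"].items())
        ]
        effective_as_of = as_of_date if as_of_date is not None else max_date
        histories.append(
            MedicationHistory(pid, mid, g["name"], fills, effective_as_of)
        )
    histories.sort(key=lambda h: (h.patient_id, h.medication_id))
    patients = {
        pid: Patient(pid, ages.get(pid))
        for pid in sorted({h.patient_id for h in histories})
    }
    return histories, patients


def parse_fulfillments(
    source: TextIO | str, as_of_date: date | None = None
) -> list[MedicationHistory]:
    """Parse a fulfillment CSV; see :func:`parse_cohort` for the dialect."""
    histories, _ = parse_cohort(source, as_of_date)
    return histories


def write_fulfillments(histories: Iterable[MedicationHistory],
                       patients: dict[str, Patient] | None = None) -> str:
    """Serialize histories back to the input CSV dialect (used by the generator)."""
    patients = patients or {}
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    header = list(REQUIRED_COLUMNS)
    include_age = any(p.age_at_first_fill is not None for p in patients.values())
    if include_age:
        header.append(AGE_COLUMN)
    writer.writerow(header)
    for h in histories:
        for f in h.fills:
            row = [f.patient_id, f.medication_id, f.medication_name,
                   f.fill_date.isoformat(), f.days_supply]
            if include_age:
                age = patients.get(f.patient_id)
                row.append("" if age is None or age.age_at_first_fill is None
                           else f"{age.age_at_first_fill:g}")
            writer.writerow(row)
    return buf.getvalue()


# --- assessment serialization -------------------------------------------------

_CSV_FIELDS = (
    "patient_id",
    "medication_id",
    "medication_name",
    "status",
    "reasons",
    "current_mpr",
    "first_fill_date",
    "last_fill_date",
    "n_gaps",
    "longest_gap_days",
    "prediction_day",
    "probability_poor",
)


def write_assessments(assessments, fmt: str = "json") -> str:
    """Serialize assessments to ``json`` (round-trip stable) or ``csv`` (one
    row per medication with status and key numbers)."""
    if fmt == "json":
        return json.dumps([a.to_dict() for a in assessments], indent=2) + "\n"
    if fmt == "csv":
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(_CSV_FIELDS)
        for a in assessments:
            d = a.to_dict()
            gaps = d["gaps"]
            pred = d.get("prediction")
            writer.writerow([
                d["patient_id"],
                d["medication_id"],
                d["medication_name"],
                d["status"],
                ";".join(d["reasons"]),
                f"{d['current_mpr']:.6f}" if d["current_mpr"] is not None else "",
                d["first_fill_date"],
                d["last_fill_date"],
                len(gaps),
                max((g["end_day"] - g["start_day"] for g in gaps), default=0),
                pred["prediction_day"] if pred else "",
                f"{pred['probability_poor']:.6f}" if pred else "",
            ])
        return buf.getvalue()
    raise ValueError(f"unknown format {fmt!r}: expected 'json' or 'csv'")


def read_assessments(text: str):
    """Parse the JSON dialect written by :func:`write_assessments`."""
    from .assessment import AdherenceAssessment

    return [AdherenceAssessment.from_dict(d) for d in json.loads(text)]


def fulfillments_to_frame(histories: Iterable[MedicationHistory]) -> pd.DataFrame:
    """Flatten histories to one row per fill, for analysis or export."""
    rows = [
        {
            "patient_id": f.patient_id,
            "medication_id": f.medication_id,
            "medication_name": f.medication_name,
            "fill_date": f.fill_date,
            "days_supply": f.days_supply,
        }
        for h in histories
        for f in h.fills
    ]
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
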