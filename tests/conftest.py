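from __future__ import annotations

from datetime import date, timedelta

import pytest

from mpr_monitor import FulfillmentRecord, MedicationHistory, Patient

START = date(2020, 1, 1)


def make_history(
    fills: list[tuple[int, int]],
    horizon: int,
    patient_id: str = "P1",
    medication_id: str = "med1",
    medication_name: str = "Testine",
) -> MedicationHistory:
    """History from (day_offset, days_supply) pairs; day 0 = first fill."""
    records = [
        FulfillmentRecord(
            patient_id, medication_id, medication_name,
            START + timedelta(days=d), s,
        )
        for d, s in fills
    ]
    return MedicationHistory(
        patient_id, medication_id, medication_name, records,
        as_of_date=START + timedelta(days=horizon),
    )


@pytest.fixture
def patient():
    return Patient("P1", 60.0)


def random_history_params(rng, max_fills: int = 8):
    """Random fill schedule: days strictly increasing from 0, supplies 1..90."""
    n = int(rng.integers(1, max_fills + 1))
    gaps = rng.integers(1, 70, size=n - 1) if n > 1 else []
    days = [0]
    for g in gaps:
        days.append(days[-1] + int(g))
    supplies = [int(s) for s in rng.integers(1, 91, size=n)]
    horizon = days[-1] + int(rng.integers(1, 120))
    return days, supplies, horizon
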