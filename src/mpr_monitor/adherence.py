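"""Possession timelines, running MPR, and refill-gap detection.

All arithmetic is on integer day offsets from the first fill (day 0),
with half-open intervals ``[start, end)``.  Two current-non-adherence
checks live here:

* the gap check — any maximal uncovered run longer than the threshold
  (default 30 days, strict) raises an alert;
* the current-MPR check — MPR strictly below 0.8 at the latest observed
  day flags the medication.

The running MPR at day *d* (d >= 1) is

    MPR(d) = (sum of days_supply over fills on days <= d) / d

i.e. total dispensed supply over days elapsed since the first fill.
It is uncapped by default: early refills can push it above 1.  The
possession timeline banks unused supply by default (carryover), so a
refill before run-out extends coverage rather than truncating it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .records import MedicationHistory

GAP_THRESHOLD_DAYS = 30
MPR_THRESHOLD = 0.8


@dataclass(frozen=True)
class GapInterval:
    """A maximal uncovered run of days, half-open ``[start_day, end_day)``.

    ``alert`` is True when the gap is strictly longer than the detection
    threshold (a 30-day gap does not alert; a 31-day gap does).
    """

    start_day: int
    end_day: int
    alert: bool = False

    def __post_init__(self):
        if self.end_day <= self.start_day:
            raise ValueError("gap interval must have positive length")

    @property
    def length(self) -> int:
        return self.end_day - self.start_day

    def to_dict(self) -> dict:
        return {"start_day": self.start_day, "end_day": self.end_day,
                "alert": self.alert}


@dataclass
class PossessionTimeline:
    """Disjoint sorted covered intervals within ``[0, horizon)``."""

    covered: list[tuple[int, int]]
    horizon: int

    def __post_init__(self):
        prev_end = -1
        for start, end in self.covered:
            if not (0 <= start < end <= self.horizon):
                raise ValueError(f"bad interval [{start}, {end}) for horizon {self.horizon}")
            if start <= prev_end:
                raise ValueError("covered intervals must be disjoint and sorted")
            prev_end = end

    @property
    def covered_days(self) -> int:
        return sum(end - start for start, end in self.covered)

    def uncovered(self) -> list[tuple[int, int]]:
        """Complement of the covered set within [0, horizon)."""
        gaps = []
        cursor = 0
        for start, end in self.covered:
            if start > cursor:
                gaps.append((cursor, start))
            cursor = end
        if cursor < self.horizon:
            gaps.append((cursor, self.horizon))
        return gaps


@dataclass
class MprSeries:
    """Running MPR sampled at strictly increasing days >= 1."""

    points: list[tuple[int, float]] = field(default_factory=list)

    @property
    def days(self) -> list[int]:
        return [d for d, _ in self.points]

    @property
    def values(self) -> list[float]:
        return [v for _, v in self.points]


def build_possession_timeline(
    history: MedicationHistory, carryover: bool = True
) -> PossessionTimeline:
    """Derive covered day intervals from a fill history.

    With ``carryover`` (default) unused supply from an early refill is
    banked: coverage runs until the cumulative supply is exhausted.
    Without it each fill covers exactly ``[fill_day, fill_day + supply)``
    and overlapping stretches merge.  Coverage is truncated at the
    observation horizon.
    """
    horizon = history.horizon
    days = history.fill_days
    supplies = history.fill_supplies
    intervals: list[tuple[int, int]] = []

    if carryover:
        run_start = days[0]
        run_end = days[0]  # exclusive end of current covered run
        for day, supply in zip(days, supplies):
            if day > run_end:  # supply lapsed before this refill
                if run_end > run_start:
                    intervals.append((run_start, run_end))
                run_start = day
                run_end = day + supply
            else:  # refill while still covered: bank the remainder
                run_end += supply
        if run_end > run_start:
            intervals.append((run_start, run_end))
    else:
        run_start, run_end = days[0], days[0] + supplies[0]
        for day, supply in zip(days[1:], supplies[1:]):
            end = day + supply
            if day > run_end:
                intervals.append((run_start, run_end))
                run_start, run_end = day, end
            else:
                run_end = max(run_end, end)
        intervals.append((run_start, run_end))

    clipped = [(s, min(e, horizon)) for s, e in intervals if s < horizon]
    clipped = [(s, e) for s, e in clipped if e > s]
    return PossessionTimeline(clipped, horizon)


def compute_mpr(history: MedicationHistory, day: int, cap_at_one: bool = False) -> float:
    """Running MPR at ``day`` (days since first fill, >= 1).

    Numerator counts supply from fills on days <= ``day`` (the patient
    possesses medication on the fill day itself); the day-0 fill is
    always included.  Uncapped unless ``cap_at_one``.
    """
    if day < 1:
        raise ValueError(f"MPR is undefined for day < 1 (got {day})")
    supply = sum(s for d, s in zip(history.fill_days, history.fill_supplies) if d <= day)
    value = supply / day
    return min(value, 1.0) if cap_at_one else value


def mpr_series(
    history: MedicationHistory, sparse: bool = False, cap_at_one: bool = False
) -> MprSeries:
    """Running MPR over the observation window.

    Dense mode samples every day in ``[1, horizon]``; sparse mode keeps
    only the breakpoints of the piecewise-hyperbolic curve (day 1, each
    fill day and the day after, run-out days, and the horizon), at which
    the two modes agree exactly.
    """
    horizon = history.horizon
    if horizon < 1:
        return MprSeries([])
    if not sparse:
        sample_days = range(1, horizon + 1)
    else:
        marks = {1, horizon}
        for d in history.fill_days:
            marks.add(max(d, 1))
            if d + 1 <= horizon:
                marks.add(d + 1)
        for start, end in build_possession_timeline(history).uncovered():
            marks.add(max(start, 1))
        sample_days = sorted(d for d in marks if 1 <= d <= horizon)
    return MprSeries([(d, compute_mpr(history, d, cap_at_one)) for d in sample_days])


def detect_gaps(
    timeline: PossessionTimeline, gap_threshold: int = GAP_THRESHOLD_DAYS
) -> list[GapInterval]:
    """All maximal uncovered runs, alerting where strictly longer than the
    threshold.  Trailing uncovered time up to the horizon counts."""
    return [
        GapInterval(start, end, alert=(end - start) > gap_threshold)
        for start, end in timeline.uncovered()
    ]


def detect_gaps_cumulative(
    history: MedicationHistory, gap_threshold: int = GAP_THRESHOLD_DAYS
) -> list[GapInterval]:
    """End-of-record gap check: elapsed time minus total dispensed supply.

    The cumulative shortfall, if positive, is reported as a single
    trailing gap ending at the horizon.  On single-fill histories this
    coincides with interval-mode detection.
    """
    shortfall = history.horizon - history.total_supply
    if shortfall <= 0:
        return []
    return [
        GapInterval(
            history.horizon - shortfall,
            history.horizon,
            alert=shortfall > gap_threshold,
        )
    ]


def check_current_mpr(
    history: MedicationHistory,
    mpr_threshold: float = MPR_THRESHOLD,
    cap_at_one: bool = False,
) -> tuple[bool, float]:
    """MPR at the latest observed day; flagged iff strictly below threshold."""
    if history.horizon < 1:
        raise ValueError("current-MPR check requires at least 1 observed day")
    value = compute_mpr(history, history.horizon, cap_at_one)
    return value < mpr_threshold, value
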