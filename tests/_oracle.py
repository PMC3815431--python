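"""Brute-force day-by-day possession oracle, independent of the package's
interval arithmetic.  A daily supply counter is decremented each day and
topped up on fill days; covered days are read off the counter directly."""

from __future__ import annotations


def simulate_possession(
    fill_days: list[int], supplies: list[int], horizon: int, carryover: bool = True
) -> list[tuple[int, int]]:
    """Covered intervals [start, end) from a literal daily simulation."""
    covered_days: set[int] = set()
    if carryover:
        fills: dict[int, int] = {}
        for d, s in zip(fill_days, supplies):
            fills[d] = fills.get(d, 0) + s
        counter = 0
        for day in range(horizon):
            counter += fills.get(day, 0)
            if counter > 0:
                covered_days.add(day)
                counter -= 1
    else:
        for d, s in zip(fill_days, supplies):
            covered_days.update(range(d, min(d + s, horizon)))
        covered_days = {d for d in covered_days if 0 <= d < horizon}
    return runs(sorted(covered_days))


def runs(days: list[int]) -> list[tuple[int, int]]:
    """Collapse a sorted day list into maximal [start, end) intervals."""
    intervals: list[tuple[int, int]] = []
    for d in days:
        if intervals and intervals[-1][1] == d:
            intervals[-1] = (intervals[-1][0], d + 1)
        else:
            intervals.append((d, d + 1))
    return intervals


def uncovered_runs(covered: list[tuple[int, int]], horizon: int) -> list[tuple[int, int]]:
    gaps = []
    cursor = 0
    for start, end in covered:
        if start > cursor:
            gaps.append((cursor, start))
        cursor = end
    if cursor < horizon:
        gaps.append((cursor, horizon))
    return gaps


def mpr_oracle(fill_days: list[int], supplies: list[int], day: int) -> float:
    """Direct evaluation of dispensed-supply-over-elapsed-days."""
    assert day >= 1
    return sum(s for d, s in zip(fill_days, supplies) if d <= day) / day
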