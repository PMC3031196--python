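"""Derivation of facility-specific scenario parameters from a case log.

Each hypothetical management scenario carries placeholders (the two
busiest ORs, the facility's usual workday start and end, the weekday with
several single-OR services, ...) that are filled in from the facility's
own data so that the cues managers see match their daily reality.  This
module derives those parameters with deterministic, fully specified rules:

* busiest ORs by case count (ties alphabetical), with OR names normalized
  so that a room called "Theatre 3" is rendered "OR Theatre 3";
* workday start = the modal first-case start time on the reference
  weekday (Thursday), rounded to the nearest 15 minutes;
* workday end = the median, over reference weekdays, of the earliest
  instant at which the number of still-running ORs drops below the
  critical fractile (0.60) of that day's active OR count, rounded up to
  the next 15 minutes;
* per-weekday median number of first-case-of-the-day starts;
* the earliest weekday on which at least three named services are each
  allocated exactly one OR.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from datetime import date, datetime, time
from pathlib import Path
from typing import Sequence

from .caselog import AdaptationConfig, CaseLog, drop_holidays, infer_holidays, select_window
from .efficiency import (
    OTHER,
    Allocation,
    RandomnessResult,
    allocate_all,
    compute_turnovers,
    compute_workloads,
    dense_daily_workloads,
    period_totals,
    randomness_check,
)
from .errors import ParameterError
from .times import WEEKDAY_NAMES, ceil_to_grid, round_to_grid, time_to_minutes


@dataclass
class FacilityProfile:
    """All facility-specific parameters needed to adapt scenarios."""

    facility_id: str
    allocations: list[Allocation] = field(default_factory=list)
    busiest_ors: list[str] = field(default_factory=list)
    workday_start: time | None = None
    workday_end: time | None = None
    scenario_end_late: time | None = None  # workday_end + 2 h, exactly
    single_or_day: int | None = None  # weekday index, Monday=0
    single_or_services: list[str] | None = None
    n_allocated_ors: int | None = None
    median_first_starts: dict[int, int] = field(default_factory=dict)
    adaptation_enabled: bool = True
    randomness: RandomnessResult | None = None
    holidays: set[date] = field(default_factory=set)
    short_window: bool = False

    def __post_init__(self) -> None:
        if self.workday_end is not None and self.scenario_end_late is not None:
            want = _add_hours(self.workday_end, 2)
            if self.scenario_end_late != want:
                raise ParameterError("scenario_end_late must equal workday_end + 2 h")
        if self.single_or_services is not None:
            if len(self.single_or_services) != 3:
                raise ParameterError("single_or_services must list exactly 3 services")
            self.single_or_services = sorted(self.single_or_services)

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize as JSON with HH:MM times and explicit nulls."""
        fmt = lambda t: None if t is None else f"{t.hour:02d}:{t.minute:02d}"  # noqa: E731
        obj = {
            "facility_id": self.facility_id,
            "busiest_ors": self.busiest_ors,
            "workday_start": fmt(self.workday_start),
            "workday_end": fmt(self.workday_end),
            "scenario_end_late": fmt(self.scenario_end_late),
            "single_or_day": None
            if self.single_or_day is None
            else WEEKDAY_NAMES[self.single_or_day],
            "single_or_services": self.single_or_services,
            "n_allocated_ors": self.n_allocated_ors,
            "median_first_starts": {
                WEEKDAY_NAMES[wd]: n for wd, n in sorted(self.median_first_starts.items())
            },
            "adaptation_enabled": self.adaptation_enabled,
            "holidays": sorted(d.isoformat() for d in self.holidays),
            "short_window": self.short_window,
            "allocations": [
                {
                    "service": a.service,
                    "weekday": WEEKDAY_NAMES[a.weekday],
                    "n_ors": a.n_ors,
                    "allocated_hours": a.allocated_hours,
                    "mean_workload": round(a.mean_workload, 3),
                    "pooled_to_other": a.pooled_to_other,
                }
                for a in self.allocations
            ],
        }
        text = json.dumps(obj, indent=2, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text


def _add_hours(t: time, hours: int) -> time:
    total = (t.hour + hours) * 60 + t.minute
    if total >= 24 * 60:
        raise ParameterError(f"time arithmetic leaves the calendar day: {t} + {hours} h")
    return time(total // 60, total % 60)


def normalize_or_name(name: str) -> str:
    """Prefix "OR " unless the name already signals a room.

    A name containing the substring "OR" (upper case) or "rm" (any case)
    is left unchanged; anything else gets "OR " prepended, so scenario
    text never refers to a bare label like "Theatre 3".
    """
    if not name or not name.strip():
        raise ParameterError("OR name must be nonempty")
    if "OR" in name or "rm" in name.lower():
        return name
    return "OR " + name


def busiest_ors(log: CaseLog, k: int = 2) -> list[str]:
    """The k ORs with the most cases, busiest first; ties alphabetical."""
    counts = Counter(r.or_name for r in log.records)
    if len(counts) < k:
        raise ParameterError(f"log has {len(counts)} OR(s); {k} requested")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [normalize_or_name(name) for name, _ in ranked[:k]]


def _reference_day_electives(log: CaseLog, config: AdaptationConfig):
    return [
        r
        for r in log.records
        if not r.urgent and r.date.weekday() == config.reference_weekday
    ]


def workday_start(log: CaseLog, config: AdaptationConfig) -> time:
    """Modal first-case start time on the reference weekday.

    Elective reference-weekday cases entering within the start-mode
    window (06:45–10:00 inclusive) are reduced to the first case per OR
    per date; each start is rounded to the nearest grid point (15 min,
    half-grid ties up) and the most common rounded time is returned, ties
    going to the earliest time.
    """
    lo, hi = config.start_mode_window
    cases = [
        r
        for r in _reference_day_electives(log, config)
        if lo <= r.enter.time() <= hi
    ]
    firsts: dict[tuple[str, date], time] = {}
    for r in sorted(cases, key=lambda r: r.enter):
        firsts.setdefault((r.or_name, r.date), r.enter.time())
    if not firsts:
        raise ParameterError("no qualifying first-case starts on the reference weekday")
    rounded = [round_to_grid(t, config.rounding_grid) for t in firsts.values()]
    counts = Counter(rounded)
    best = max(counts.items(), key=lambda kv: (kv[1], -time_to_minutes(kv[0])))
    return best[0]


def workday_end(log: CaseLog, config: AdaptationConfig) -> time:
    """Typical end of the staffed workday on the reference weekday.

    For each reference-weekday date, let m be the number of ORs with at
    least one elective case; scanning elective exits in time order, take
    the earliest instant at which the number of ORs still running is
    below ``critical_fractile * m`` (0.60 m at the default cost ratio).
    An OR counts as running until its last elective case of the date has
    exited — a room momentarily between cases has not finished its day.
    The median of these per-date times (even count: the earlier central
    value) is rounded *up* to the next grid point — an exact grid time is
    unchanged, one minute past it moves up a full step.
    """
    per_date: dict[date, list] = {}
    for r in _reference_day_electives(log, config):
        per_date.setdefault(r.date, []).append(r)
    day_times: list[time] = []
    for d, cases in sorted(per_date.items()):
        m = len({c.or_name for c in cases})
        threshold = config.critical_fractile * m
        last_exit: dict[str, datetime] = {}
        for c in cases:
            if c.or_name not in last_exit or c.exit > last_exit[c.or_name]:
                last_exit[c.or_name] = c.exit
        found = None
        for c in sorted(cases, key=lambda c: c.exit):
            t = c.exit
            running = sum(1 for e in last_exit.values() if e > t)
            if running < threshold:
                found = t.time()
                break
        if found is not None:
            day_times.append(found)
    if not day_times:
        raise ParameterError("no qualifying reference-weekday dates for workday end")
    day_times.sort()
    median = day_times[(len(day_times) - 1) // 2]  # even count: earlier central value
    return ceil_to_grid(median, config.rounding_grid)


def first_case_counts(log: CaseLog, config: AdaptationConfig) -> dict[int, int]:
    """Median number of first-case-of-the-day starts per weekday.

    Considers all cases (urgent included) entering within the first-case
    window (06:45–09:30 inclusive), keeps the first such case per OR per
    date, counts them per date, and returns the per-weekday median count
    (even count: the lower median, keeping the result integral).
    """
    lo, hi = config.first_case_window
    firsts: dict[tuple[str, date], time] = {}
    for r in sorted(log.records, key=lambda r: r.enter):
        if lo <= r.enter.time() <= hi:
            firsts.setdefault((r.or_name, r.date), r.enter.time())
    per_date: dict[date, int] = {}
    for (or_name, d) in firsts:
        per_date[d] = per_date.get(d, 0) + 1
    by_weekday: dict[int, list[int]] = {}
    for d, n in per_date.items():
        by_weekday.setdefault(d.weekday(), []).append(n)
    out: dict[int, int] = {}
    for wd, counts in by_weekday.items():
        counts.sort()
        out[wd] = counts[(len(counts) - 1) // 2]  # lower median
    return out


def single_or_selection(
    allocations: Sequence[Allocation],
) -> tuple[int, list[str], int] | None:
    """Earliest weekday with >= 3 named services allocated exactly one OR.

    Weekdays are ordered Monday-first.  Returns (weekday, first three
    qualifying services alphabetically, total ORs allocated to named
    services that weekday, OTHER excluded), or None when no weekday
    qualifies — in which case the dependent scenario is simply excluded
    from the facility's collection.
    """
    by_weekday: dict[int, list[Allocation]] = {}
    for a in allocations:
        if a.service != OTHER and not a.pooled_to_other:
            by_weekday.setdefault(a.weekday, []).append(a)
    for wd in sorted(by_weekday):
        singles = sorted(a.service for a in by_weekday[wd] if a.n_ors == 1)
        if len(singles) >= 3:
            n_allocated = sum(a.n_ors for a in by_weekday[wd])
            return wd, singles[:3], n_allocated
    return None


def build_profile(log: CaseLog, config: AdaptationConfig | None = None) -> FacilityProfile:
    """Run the full derivation pipeline on a validated case log.

    Windows the log to the most recent 9 four-week periods, infers and
    drops holidays, computes turnovers/workloads/allocations, runs the
    stationarity check (a failure disables adaptation so the facility
    receives non-adapted scenario text), and derives every scenario
    parameter.  Parameters whose preconditions fail are left None; the
    scenarios that need them are excluded rather than fabricated.
    """
    config = config or AdaptationConfig()
    windowed = select_window(log, config)
    holidays = infer_holidays(windowed, config)
    clean = drop_holidays(windowed, holidays)

    turnovers = compute_turnovers(clean, config)
    workloads = compute_workloads(clean, turnovers, config)
    daily = dense_daily_workloads(workloads, clean, holidays)
    allocations = allocate_all(daily, config)
    randomness = randomness_check(period_totals(workloads, config), config)

    profile = FacilityProfile(
        facility_id=log.facility_id,
        allocations=allocations,
        adaptation_enabled=randomness.passed,
        randomness=randomness,
        holidays=holidays,
        short_window=windowed.short_window,
    )
    try:
        profile.busiest_ors = busiest_ors(clean, k=2)
    except ParameterError:
        pass
    try:
        profile.workday_start = workday_start(clean, config)
    except ParameterError:
        pass
    try:
        profile.workday_end = workday_end(clean, config)
        profile.scenario_end_late = _add_hours(profile.workday_end, 2)
    except ParameterError:
        pass
    profile.median_first_starts = first_case_counts(clean, config)
    selection = single_or_selection(allocations)
    if selection is not None:
        profile.single_or_day, profile.single_or_services, profile.n_allocated_ors = selection
    return profile
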