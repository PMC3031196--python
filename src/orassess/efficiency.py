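"""Turnover times, service workloads, and OR allocations maximizing efficiency.

The central quantity is the *inefficiency of use of OR time* for one
service on one weekday, given an allocation of A staffed hours:

    inefficiency(A) = sum over days d of  (A - w_d)+  +  r * (w_d - A)+

where ``w_d`` is the service's elective workload (case-hours plus
attributed turnover-hours) on day d and ``r > 1`` is the cost of an
over-utilized hour relative to an under-utilized one (default 1.5).
Inefficiency is reported in under-utilized-hour equivalents.  The optimal
allocation is found by direct search over 0, 1, 2, ... ORs; as the
staffing granularity shrinks this search converges to the newsvendor
solution, the r/(1+r) quantile of daily workload (the 0.60 critical
fractile at r = 1.5).

Service/weekday combinations whose mean daily workload falls below the
configured break-even (5.60 h by default) are not given their own OR but
pooled into the first-scheduled-first-served OTHER pseudo-service.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .caselog import AdaptationConfig, CaseLog
from .errors import ValidationError

#: Name of the pooled open-posting pseudo-service.
OTHER = "OTHER"


@dataclass(frozen=True)
class TurnoverRecord:
    """Gap between two sequential cases in the same OR on the same date."""

    or_name: str
    date: date
    raw_minutes: float
    capped_minutes: float
    following_case_id: str
    following_service: str
    following_urgent: bool


@dataclass(frozen=True)
class ServiceDayWorkload:
    """Elective workload of one service on one date, in hours."""

    service: str
    date: date
    weekday: int  # Monday=0
    hours: float
    period: int | None = None


@dataclass(frozen=True)
class Allocation:
    """Chosen number of ORs for one service on one weekday."""

    service: str
    weekday: int
    n_ors: int
    allocated_hours: float
    inefficiency: float
    mean_workload: float
    pooled_to_other: bool = False


@dataclass(frozen=True)
class RandomnessResult:
    """Outcome of the workload-stationarity (no-trend) check."""

    passed: bool
    statistic: float
    pvalue: float
    n_periods: int
    skipped: bool = False


def compute_turnovers(log: CaseLog, config: AdaptationConfig) -> list[TurnoverRecord]:
    """Turnover between each pair of sequential cases in one OR on one day.

    The raw gap runs from the first patient's exit to the next patient's
    entry; gaps longer than ``turnover_cap`` minutes (90 by default) are
    capped at the cap, since very long gaps are scheduled delays rather
    than cleanup/setup time.  OR-days with a single case yield no record.
    """
    out: list[TurnoverRecord] = []
    frame = log.to_frame()
    if frame.empty:
        return out
    for (_or_name, _day), group in frame.groupby(["or_name", "date"], sort=True):
        group = group.sort_values("enter")
        prev_exit = None
        for row in group.itertuples(index=False):
            if prev_exit is not None:
                raw = (row.enter - prev_exit).total_seconds() / 60.0
                out.append(
                    TurnoverRecord(
                        or_name=row.or_name,
                        date=row.date,
                        raw_minutes=raw,
                        capped_minutes=min(raw, config.turnover_cap),
                        following_case_id=row.case_id,
                        following_service=row.service,
                        following_urgent=bool(row.urgent),
                    )
                )
            prev_exit = row.exit
    return out


def compute_workloads(
    log: CaseLog,
    turnovers: Sequence[TurnoverRecord],
    config: AdaptationConfig,
) -> list[ServiceDayWorkload]:
    """Per-service per-date elective workload in hours.

    Workload is the sum of elective case durations plus the capped
    turnover times attributed to the service; a turnover is attributed to
    the service of the *following* case (the gap prepares the room for
    it).  Urgent cases contribute nothing, including their preceding
    turnover.  Dates on which a service had cases but all were urgent
    still appear, with zero hours.
    """
    hours: dict[tuple[str, date], float] = {}
    for r in log.records:
        key = (r.service, r.date)
        hours.setdefault(key, 0.0)
        if not r.urgent:
            hours[key] += r.duration_hours
    for t in turnovers:
        if t.following_urgent:
            continue
        key = (t.following_service, t.date)
        if key in hours:
            hours[key] += t.capped_minutes / 60.0
    return [
        ServiceDayWorkload(
            service=svc,
            date=d,
            weekday=d.weekday(),
            hours=h,
            period=_period_of(log, svc, d),
        )
        for (svc, d), h in sorted(hours.items())
    ]


def _period_of(log: CaseLog, service: str, d: date) -> int | None:
    if log.window_start is None:
        return None
    return (d - log.window_start).days // 28 + 1


def inefficiency_of_use(
    workloads: Iterable[float], allocated_hours: float, config: AdaptationConfig
) -> float:
    """Total inefficiency over days, in under-utilized-hour equivalents.

    Sum of under-utilized hours (allocation minus workload, when positive)
    at unit cost plus over-utilized hours at ``cost_ratio`` times that.
    """
    if allocated_hours < 0:
        raise ValueError("allocated_hours must be nonnegative")
    w = np.asarray(list(workloads), dtype=float)
    under = np.clip(allocated_hours - w, 0.0, None)
    over = np.clip(w - allocated_hours, 0.0, None)
    return float(under.sum() + config.cost_ratio * over.sum())


def dense_daily_workloads(
    workloads: Sequence[ServiceDayWorkload],
    log: CaseLog,
    holidays: set[date] | frozenset[date] = frozenset(),
) -> dict[tuple[str, int], dict[date, float]]:
    """Expand sparse workloads to every non-holiday date in the window.

    Returns {(service, weekday): {date: hours}} where dates with no cases
    for the service count as zero workload — a day the service did not
    operate is a zero-demand day, not a missing observation.  Weekend
    dates are included only when some service actually worked them.
    """
    if log.window_start is None or log.window_end is None:
        raise ValidationError("workload densification requires a windowed log")
    all_dates: list[date] = []
    d = log.window_start
    worked_weekend_dates = {w.date for w in workloads if w.weekday >= 5}
    while d <= log.window_end:
        if d not in holidays and (d.weekday() < 5 or d in worked_weekend_dates):
            all_dates.append(d)
        d += timedelta(days=1)
    services = sorted({w.service for w in workloads})
    sparse = {(w.service, w.date): w.hours for w in workloads}
    dense: dict[tuple[str, int], dict[date, float]] = {}
    for svc in services:
        for day in all_dates:
            key = (svc, day.weekday())
            dense.setdefault(key, {})[day] = sparse.get((svc, day), 0.0)
    return dense


def pool_low_workload_services(
    daily: Mapping[tuple[str, int], Mapping[date, float]],
    config: AdaptationConfig,
) -> tuple[dict[tuple[str, int], dict[date, float]], list[tuple[str, int]]]:
    """Pool low-workload service/weekday pairs into the OTHER pseudo-service.

    A pair whose mean daily workload is strictly below
    ``pooling_threshold`` (5.60 h) is not worth its own OR: its workload
    is added to OTHER for that weekday.  Returns the retained mapping
    (with OTHER rows added) and the list of pooled (service, weekday)
    pairs.
    """
    retained: dict[tuple[str, int], dict[date, float]] = {}
    pooled: list[tuple[str, int]] = []
    other: dict[int, dict[date, float]] = {}
    for (svc, wd), by_date in daily.items():
        mean = float(np.mean(list(by_date.values()))) if by_date else 0.0
        if mean < config.pooling_threshold:
            pooled.append((svc, wd))
            acc = other.setdefault(wd, {})
            for day, h in by_date.items():
                acc[day] = acc.get(day, 0.0) + h
        else:
            retained[(svc, wd)] = dict(by_date)
    for wd, by_date in other.items():
        retained[(OTHER, wd)] = by_date
    return retained, sorted(pooled)


def allocate_ors(
    daily_workloads: Sequence[float],
    config: AdaptationConfig,
    service: str = "",
    weekday: int = 0,
) -> Allocation:
    """Choose the number of ORs minimizing total inefficiency of use.

    Evaluates 0, 1, 2, ... ORs (``allocated_hours = k * staffed_hours``)
    and keeps the smallest-inefficiency choice; ties break toward fewer
    ORs.  The search stops once the allocation exceeds the maximum daily
    workload by a full staffed OR, beyond which inefficiency can only
    grow.
    """
    w = [float(x) for x in daily_workloads]
    if not w:
        raise ValidationError("allocate_ors requires at least one daily workload")
    best_k, best_cost = 0, inefficiency_of_use(w, 0.0, config)
    k = 0
    limit = max(w) + config.staffed_hours_per_or
    while (k * config.staffed_hours_per_or) <= limit:
        k += 1
        cost = inefficiency_of_use(w, k * config.staffed_hours_per_or, config)
        if cost < best_cost:
            best_k, best_cost = k, cost
    return Allocation(
        service=service,
        weekday=weekday,
        n_ors=best_k,
        allocated_hours=best_k * config.staffed_hours_per_or,
        inefficiency=best_cost,
        mean_workload=float(np.mean(w)),
    )


def allocate_all(
    daily: Mapping[tuple[str, int], Mapping[date, float]],
    config: AdaptationConfig,
) -> list[Allocation]:
    """Pool low-workload pairs, then allocate ORs to every retained pair.

    Pooled (service, weekday) pairs are reported with ``n_ors = 0`` and
    ``pooled_to_other = True``; the OTHER pseudo-service carries their
    combined workload and receives its own allocation per weekday.
    """
    retained, pooled = pool_low_workload_services(daily, config)
    out: list[Allocation] = []
    for (svc, wd), by_date in sorted(retained.items()):
        out.append(allocate_ors(list(by_date.values()), config, service=svc, weekday=wd))
    for svc, wd in pooled:
        by_date = daily[(svc, wd)]
        out.append(
            Allocation(
                service=svc,
                weekday=wd,
                n_ors=0,
                allocated_hours=0.0,
                inefficiency=float("nan"),
                mean_workload=float(np.mean(list(by_date.values()))) if by_date else 0.0,
                pooled_to_other=True,
            )
        )
    return out


def randomness_check(
    period_totals: Sequence[float], config: AdaptationConfig
) -> RandomnessResult:
    """Test the stationarity assumption: no trend in workload over periods.

    Spearman rank correlation between the four-week period index
    (1..n_periods) and the per-period workload totals, two-sided.  The
    check fails when p < ``trend_alpha``; a failing facility gets
    non-adapted scenario text, since its derived parameters would not
    describe a stable operating state.  Constant totals pass (zero
    correlation); fewer than 3 periods skips the check with a warning.
    """
    totals = np.asarray(list(period_totals), dtype=float)
    n = len(totals)
    if n < 3:
        warnings.warn("randomness check skipped: fewer than 3 periods", stacklevel=2)
        return RandomnessResult(True, float("nan"), float("nan"), n, skipped=True)
    if np.ptp(totals) == 0.0:
        return RandomnessResult(True, 0.0, 1.0, n)
    rho, p = stats.spearmanr(np.arange(1, n + 1), totals)
    if np.isnan(p):
        p = 1.0
    return RandomnessResult(bool(p >= config.trend_alpha), float(rho), float(p), n)


def period_totals(workloads: Sequence[ServiceDayWorkload], config: AdaptationConfig) -> list[float]:
    """Total facility workload per four-week period, for the trend check."""
    acc: dict[int, float] = {}
    for w in workloads:
        if w.period is not None:
            acc[min(w.period, config.n_periods)] = acc.get(min(w.period, config.n_periods), 0.0) + w.hours
    return [acc.get(i, 0.0) for i in range(1, max(acc, default=0) + 1)]
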