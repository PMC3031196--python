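"""Case-log input, validation, windowing, and holiday inference.

A facility case log has one row per surgical case: the OR it was performed
in, the scheduling service, the surgeon, patient room-entry and room-exit
timestamps, and an urgent/elective flag.  Everything downstream — turnover
times, service workloads, OR allocations, scenario parameters — derives
from this table, so this module is strict about validation: rows violating
per-case invariants are dropped with a per-row report, and two cases
overlapping in the same OR on the same date abort the read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import SchemaError, ValidationError
from .times import parse_clock

REQUIRED_COLUMNS = ("case_id", "or_name", "service", "surgeon", "enter", "exit", "urgent")

_TRUE_TOKENS = {"1", "true", "t", "yes", "y"}
_FALSE_TOKENS = {"0", "false", "f", "no", "n"}


@dataclass(frozen=True)
class CaseRecord:
    """One surgical case: patient in the OR from ``enter`` to ``exit``.

    ``exit`` must be strictly after ``enter`` and on the same calendar
    date; overnight cases are rejected because every downstream statistic
    groups cases by calendar date.
    """

    case_id: str
    or_name: str
    service: str
    surgeon: str
    enter: datetime
    exit: datetime
    urgent: bool

    def __post_init__(self) -> None:
        if self.exit <= self.enter:
            raise ValidationError(
                f"case {self.case_id}: exit {self.exit} not after enter {self.enter}"
            )
        if self.exit.date() != self.enter.date():
            raise ValidationError(
                f"case {self.case_id}: enter and exit on different dates (overnight case)"
            )

    @property
    def date(self) -> date:
        return self.enter.date()

    @property
    def duration_hours(self) -> float:
        return (self.exit - self.enter).total_seconds() / 3600.0


@dataclass
class CaseLog:
    """A validated, ordered collection of :class:`CaseRecord`.

    ``window_start``/``window_end`` are the (inclusive) date bounds of the
    analysis window once :func:`select_window` has run; before windowing
    they simply span the data.  ``periods`` maps each retained case_id to
    its four-week period index (1 = oldest) after windowing.
    """

    records: list[CaseRecord]
    facility_id: str = "facility"
    window_start: date | None = None
    window_end: date | None = None
    short_window: bool = False
    periods: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: (r.date, r.or_name, r.enter, r.case_id))
        _check_no_overlaps(self.records)
        if self.records:
            if self.window_start is None:
                self.window_start = min(r.date for r in self.records)
            if self.window_end is None:
                self.window_end = max(r.date for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Return the log as a tidy DataFrame (one row per case)."""
        return pd.DataFrame(
            {
                "case_id": [r.case_id for r in self.records],
                "or_name": [r.or_name for r in self.records],
                "service": [r.service for r in self.records],
                "surgeon": [r.surgeon for r in self.records],
                "enter": [r.enter for r in self.records],
                "exit": [r.exit for r in self.records],
                "urgent": [r.urgent for r in self.records],
                "date": [r.date for r in self.records],
                "duration_hours": [r.duration_hours for r in self.records],
            }
        )

    def filtered(self, keep: Iterable[CaseRecord]) -> "CaseLog":
        keep = list(keep)
        return replace(self, records=keep, periods=dict(self.periods))


def _check_no_overlaps(records: Sequence[CaseRecord]) -> None:
    """No two cases in the same OR on the same date may overlap in time."""
    by_or_day: dict[tuple[str, date], list[CaseRecord]] = {}
    for r in records:
        by_or_day.setdefault((r.or_name, r.date), []).append(r)
    for (_, _), group in by_or_day.items():
        group = sorted(group, key=lambda r: r.enter)
        for prev, nxt in zip(group, group[1:]):
            if nxt.enter < prev.exit:
                raise ValidationError(
                    f"cases {prev.case_id} and {nxt.case_id} overlap in "
                    f"{prev.or_name} on {prev.date}"
                )


@dataclass(frozen=True)
class AdaptationConfig:
    """Numeric constants of the adaptation method.

    The defaults are the method's published operating point: over-utilized
    OR time costs 1.5 times an under-utilized hour, service/weekday
    combinations averaging under 5.60 h of daily workload are pooled into
    the open-posting OTHER service, turnovers are capped at 90 min, and
    statistics run over the most recent 9 four-week periods of data.
    ``staffed_hours_per_or``, ``holiday_fraction`` and ``trend_alpha`` are
    this package's own plumbing knobs (hours staffed per allocated OR, the
    fraction-of-weekday-median cutoff for holiday inference, and the
    significance level of the workload stationarity check).
    """

    cost_ratio: float = 1.5
    pooling_threshold: float = 5.60  # hours
    turnover_cap: float = 90.0  # minutes
    n_periods: int = 9
    first_case_window: tuple[time, time] = (time(6, 45), time(9, 30))
    start_mode_window: tuple[time, time] = (time(6, 45), time(10, 0))
    rounding_grid: int = 15  # minutes
    reference_weekday: int = 3  # Monday=0 .. Thursday=3
    staffed_hours_per_or: float = 8.0
    holiday_fraction: float = 0.25
    trend_alpha: float = 0.01

    def __post_init__(self) -> None:
        if self.cost_ratio <= 1:
            raise ValueError("cost_ratio must exceed 1: an over-utilized hour is always costlier")
        for name in ("pooling_threshold", "turnover_cap", "staffed_hours_per_or"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_periods < 1 or self.rounding_grid < 1:
            raise ValueError("n_periods and rounding_grid must be positive integers")
        if not 0 < self.holiday_fraction < 1:
            raise ValueError("holiday_fraction must lie in (0, 1)")
        if not 0 < self.trend_alpha < 1:
            raise ValueError("trend_alpha must lie in (0, 1)")
        if not 0 <= self.reference_weekday <= 6:
            raise ValueError("reference_weekday must be 0 (Monday) .. 6 (Sunday)")

    @property
    def critical_fractile(self) -> float:
        """Newsvendor quantile r/(1+r) balancing under- vs over-utilization."""
        return self.cost_ratio / (1.0 + self.cost_ratio)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AdaptationConfig":
        """Load a config from a YAML file mirroring the field names."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        for key, value in raw.items():
            if key in ("first_case_window", "start_mode_window"):
                kwargs[key] = (parse_clock(value[0]), parse_clock(value[1]))
            elif key == "reference_weekday" and isinstance(value, str):
                from .times import WEEKDAY_NAMES

                kwargs[key] = WEEKDAY_NAMES.index(value.capitalize())
            else:
                kwargs[key] = value
        unknown = set(kwargs) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)


def _parse_bool(token: object) -> bool:
    s = str(token).strip().lower()
    if s in _TRUE_TOKENS:
        return True
    if s in _FALSE_TOKENS:
        return False
    raise ValueError(f"unparseable urgent flag: {token!r}")


def read_caselog(
    path: str | Path,
    facility_id: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> CaseLog:
    """Read and validate a case log from a comma-separated file.

    The file needs a header row naming the columns ``case_id, or_name,
    service, surgeon, enter, exit, urgent`` (``column_map`` can rename
    foreign headers onto these), with ISO-8601 timestamps and urgent in
    {0, 1, true, false}.  Rows violating per-case invariants (exit not
    after enter, overnight span, unparseable timestamp) are dropped with a
    logged per-row report; overlapping cases in one OR raise
    :class:`~orassess.errors.ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"case-log file not found: {path}")
    df = pd.read_csv(path, dtype=str)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"case log {path} missing required columns: {missing}")

    records: list[CaseRecord] = []
    rejected: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            rec = CaseRecord(
                case_id=str(row.case_id),
                or_name=str(row.or_name),
                service=str(row.service),
                surgeon=str(row.surgeon),
                enter=datetime.fromisoformat(str(row.enter)),
                exit=datetime.fromisoformat(str(row.exit)),
                urgent=_parse_bool(row.urgent),
            )
        except (ValidationError, ValueError) as exc:
            rejected.append(f"line {i}: {exc}")
            continue
        records.append(rec)
    if rejected:
        report = "; ".join(rejected)
        warnings.warn(f"rejected {len(rejected)} case-log row(s): {report}", stacklevel=2)
    return CaseLog(records=records, facility_id=facility_id or path.stem)


def write_caselog(log: CaseLog, path: str | Path) -> None:
    """Write a log in the CSV dialect that :func:`read_caselog` reads."""
    df = log.to_frame()[list(REQUIRED_COLUMNS)].copy()
    df["enter"] = [r.enter.strftime("%Y-%m-%dT%H:%M") for r in log.records]
    df["exit"] = [r.exit.strftime("%Y-%m-%dT%H:%M") for r in log.records]
    df["urgent"] = df["urgent"].astype(int)
    df.to_csv(path, index=False)


def select_window(log: CaseLog, config: AdaptationConfig) -> CaseLog:
    """Keep the most recent ``n_periods`` four-week periods of data.

    The window is the half-open span of ``n_periods * 28`` days ending the
    day after the latest case date, i.e. dates in
    ``[latest - 28*n + 1, latest]``.  Each retained case is assigned its
    four-week period index 1..n (1 = oldest).  A log spanning fewer days
    than the window is returned whole with ``short_window`` set.
    """
    if not log.records:
        raise ValidationError("cannot window an empty case log")
    span_days = config.n_periods * 28
    latest = max(r.date for r in log.records)
    earliest = min(r.date for r in log.records)
    start = latest - timedelta(days=span_days - 1)
    short = earliest > start
    if short:
        warnings.warn(
            f"case log spans {(latest - earliest).days + 1} days, fewer than the "
            f"{span_days}-day window; using all data",
            stacklevel=2,
        )
        start = earliest
    kept = [r for r in log.records if start <= r.date <= latest]
    periods = {
        r.case_id: min((r.date - start).days // 28 + 1, config.n_periods) for r in kept
    }
    return replace(
        log,
        records=kept,
        window_start=start,
        window_end=latest,
        short_window=short,
        periods=periods,
    )


def infer_holidays(log: CaseLog, config: AdaptationConfig) -> set[date]:
    """Infer holidays and slow-down days from very low weekday workloads.

    A Monday–Friday date inside the window is flagged when its total
    facility case-hours fall below ``holiday_fraction`` times the median
    case-hours of that same weekday across the window (weekdays with zero
    cases count as zero hours).  Flagged dates are excluded from all
    downstream statistics.
    """
    if log.window_start is None or log.window_end is None:
        return set()
    hours_by_date: dict[date, float] = {}
    d = log.window_start
    while d <= log.window_end:
        if d.weekday() < 5:
            hours_by_date[d] = 0.0
        d += timedelta(days=1)
    for r in log.records:
        if r.date.weekday() < 5:
            hours_by_date[r.date] = hours_by_date.get(r.date, 0.0) + r.duration_hours

    by_weekday: dict[int, list[float]] = {}
    for day, hours in hours_by_date.items():
        by_weekday.setdefault(day.weekday(), []).append(hours)
    medians = {wd: float(pd.Series(vals).median()) for wd, vals in by_weekday.items()}

    return {
        day
        for day, hours in hours_by_date.items()
        if medians[day.weekday()] > 0 and hours < config.holiday_fraction * medians[day.weekday()]
    }


def drop_holidays(log: CaseLog, holidays: set[date]) -> CaseLog:
    """Return the log without cases on the given dates."""
    return log.filtered(r for r in log.records if r.date not in holidays)
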