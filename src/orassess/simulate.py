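"""Seeded synthetic case-log generation.

Real OR case logs are confidential, so every stage of the pipeline is
exercised against simulated logs carrying the statistical structure the
analysis assumes: per-service per-weekday workload targets with day-to-day
noise, right-skewed (lognormal) case durations, truncated-normal turnover
gaps, occasional urgent add-on cases, and configured holiday slow-down
days with no elective activity.

For each workday and service the generator draws a target elective
workload (normal, truncated at zero) and packs cases into the service's
OR(s) starting at ``first_start``: cases separated by turnover gaps are
appended while doing so keeps the realized workload closer to the target
than stopping would, so the realized daily workload is an approximately
unbiased, granular version of the target.  Urgent cases are generated *in
addition* to the elective target (each elective case spawns a trailing
urgent case with probability ``urgent_fraction``), so that the elective
workload statistics downstream recover the configured means regardless of
the urgent load.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, time, timedelta
from typing import Mapping

import numpy as np

from .caselog import CaseLog, CaseRecord
from .errors import GenerationError


@dataclass(frozen=True)
class ServiceSpec:
    """Generative parameters for one scheduling service.

    ``weekday_hours`` maps weekday index (Monday=0 .. Friday=4) to the
    mean elective daily workload in hours; missing weekdays mean the
    service does not operate that day.
    """

    name: str
    or_names: tuple[str, ...]
    weekday_hours: Mapping[int, float]
    workload_sd: float = 1.0
    case_mean_hours: float = 1.5
    case_sd_hours: float = 0.75

    def __post_init__(self) -> None:
        if not self.or_names:
            raise GenerationError(f"service {self.name} has no OR")
        if self.workload_sd < 0 or self.case_mean_hours <= 0 or self.case_sd_hours < 0:
            raise GenerationError(f"service {self.name}: invalid workload/duration parameters")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a synthetic facility; a fixed seed fixes the output."""

    services: tuple[ServiceSpec, ...]
    turnover_mean: float = 30.0  # minutes
    turnover_sd: float = 10.0
    urgent_fraction: float = 0.10
    n_periods: int = 9
    first_start: time = time(7, 30)
    holidays: frozenset[date] = frozenset()
    seed: int = 0
    end_date: date = date(2025, 6, 27)  # a Friday, so the window ends on a workday
    facility_id: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.services:
            raise GenerationError("at least one service is required")
        if not 0 <= self.urgent_fraction <= 1:
            raise GenerationError("urgent_fraction must lie in [0, 1]")
        if self.turnover_mean < 0 or self.turnover_sd < 0:
            raise GenerationError("turnover parameters must be nonnegative")


def default_simulation_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A mid-size facility: five services, one OR each, Monday–Friday.

    Workload means span busy (9 h) to marginal (5 h) services so that
    pooling, allocation, and single-OR selection all have material to
    work with.
    """
    weekdays = range(5)
    specs = tuple(
        ServiceSpec(
            name=name,
            or_names=(or_name,),
            weekday_hours={wd: hours for wd in weekdays},
            workload_sd=1.0,
        )
        for name, or_name, hours in (
            ("General Surgery", "OR 1", 9.0),
            ("Orthopedics", "OR 2", 8.0),
            ("Urology", "OR 3", 7.5),
            ("Gynecology", "OR 4", 7.0),
            ("Pain Medicine", "OR 5", 5.0),
        )
    )
    return SimulationConfig(services=specs, seed=seed, **overrides)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _pack_day(
    rng: np.random.Generator,
    spec: ServiceSpec,
    sim: SimulationConfig,
    or_name: str,
    day: date,
    target_hours: float,
) -> list[tuple[datetime, datetime, bool]]:
    """Pack (enter, exit, urgent) triples into one OR toward a workload target."""
    day_start = datetime.combine(day, sim.first_start)
    day_end = datetime.combine(day, time(23, 59))
    available = (day_end - day_start).total_seconds() / 3600.0
    if target_hours > available:
        raise GenerationError(
            f"{spec.name} target workload {target_hours:.1f} h on {day} exceeds "
            f"the {available:.1f} h available in {or_name}"
        )
    mu, sigma = _lognormal_params(spec.case_mean_hours, spec.case_sd_hours)
    cases: list[tuple[datetime, datetime, bool]] = []
    cursor = day_start
    realized = 0.0
    while True:
        duration = float(rng.lognormal(mu, sigma))
        gap_min = float(np.clip(rng.normal(sim.turnover_mean, sim.turnover_sd), 0.0, None))
        increment = duration if not cases else duration + gap_min / 60.0
        # include the case only if it brings the realized workload closer
        # to the target than stopping here would
        if abs(realized + increment - target_hours) > abs(realized - target_hours):
            break
        enter = cursor if not cases else cursor + timedelta(minutes=gap_min)
        exit_ = enter + timedelta(hours=duration)
        if exit_ >= day_end:
            break
        cases.append((enter, exit_, False))
        cursor = exit_
        realized += increment
    # urgent add-ons trail the elective block and do not count toward it
    n_urgent = int(rng.binomial(len(cases), sim.urgent_fraction)) if cases else 0
    for _ in range(n_urgent):
        gap_min = float(np.clip(rng.normal(sim.turnover_mean, sim.turnover_sd), 0.0, None))
        duration = float(rng.lognormal(mu, sigma))
        enter = cursor + timedelta(minutes=gap_min)
        exit_ = enter + timedelta(hours=duration)
        if exit_ >= day_end:
            break
        cases.append((enter, exit_, True))
        cursor = exit_
    return cases


def simulate_caselog(sim: SimulationConfig) -> CaseLog:
    """Generate a seeded case log spanning ``n_periods`` four-week periods."""
    rng = np.random.default_rng(sim.seed)
    span_days = sim.n_periods * 28
    start = sim.end_date - timedelta(days=span_days - 1)
    surgeons = {spec.name: f"Dr. {spec.name.split()[0]}" for spec in sim.services}

    records: list[CaseRecord] = []
    counter = 0
    for offset in range(span_days):
        day = start + timedelta(days=offset)
        if day.weekday() >= 5 or day in sim.holidays:
            continue
        for spec in sim.services:
            mean = spec.weekday_hours.get(day.weekday())
            if mean is None:
                continue
            target = max(0.0, float(rng.normal(mean, spec.workload_sd)))
            per_or = target / len(spec.or_names)
            for or_name in spec.or_names:
                for enter, exit_, urgent in _pack_day(rng, spec, sim, or_name, day, per_or):
                    counter += 1
                    records.append(
                        CaseRecord(
                            case_id=f"C{counter:06d}",
                            or_name=or_name,
                            service=spec.name,
                            surgeon=surgeons[spec.name],
                            enter=enter,
                            exit=exit_,
                            urgent=urgent,
                        )
                    )
    return CaseLog(records=records, facility_id=sim.facility_id)


def fixture_small() -> CaseLog:
    """Deterministic hand-built two-week, 3-OR, 3-service log for unit tests.

    Contains exactly one 120-minute turnover gap (OR 1 on the first
    Tuesday), one urgent case (OR 2 on the first Wednesday), and one
    holiday-like date with zero cases (the first Friday).
    """
    holiday = date(2025, 3, 7)  # first Friday: no cases at all
    long_gap_day = date(2025, 3, 4)  # first Tuesday: 120-min gap in OR 1
    urgent_day = date(2025, 3, 5)

    records: list[CaseRecord] = []
    counter = 0

    def add(or_name: str, service: str, surgeon: str, day: date,
            h1: int, m1: int, h2: int, m2: int, urgent: bool = False) -> None:
        nonlocal counter
        counter += 1
        records.append(
            CaseRecord(
                case_id=f"F{counter:03d}",
                or_name=or_name,
                service=service,
                surgeon=surgeon,
                enter=datetime.combine(day, time(h1, m1)),
                exit=datetime.combine(day, time(h2, m2)),
                urgent=urgent,
            )
        )

    day = date(2025, 3, 3)  # a Monday
    for _ in range(12):
        if day.weekday() < 5 and day != holiday:
            add("OR 1", "General Surgery", "Dr. Adams", day, 7, 30, 10, 30)
            if day == long_gap_day:
                add("OR 1", "General Surgery", "Dr. Adams", day, 12, 30, 14, 30)
            else:
                add("OR 1", "General Surgery", "Dr. Adams", day, 11, 0, 14, 30)
            add("OR 2", "Orthopedics", "Dr. Brown", day, 7, 30, 12, 30)
            add("Rm 3", "Pain Medicine", "Dr. Chen", day, 8, 0, 9, 30)
            if day == urgent_day:
                add("OR 2", "Orthopedics", "Dr. Brown", day, 14, 0, 15, 0, urgent=True)
        day += timedelta(days=1)
    return CaseLog(records=records, facility_id="fixture-small")
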