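"""Normative decision rules used inside the scenarios.

Two operational decisions have closed-form efficiency-maximizing answers:

* *Releasing allocated OR time.*  When a service has filled its allocated
  time and wants to schedule another case, the case goes into the time of
  the service with the most allocated-but-unscheduled OR time — the best
  available proxy for the service expected to have the most
  under-utilized time on the day of surgery.

* *Day-of-surgery prioritization.*  When two ORs both expect to be ready
  for their next patient, preparing the patient for the OR with the most
  expected over-utilized time comes first, because on the day of surgery
  efficiency is maximized by minimizing over-utilized OR time.  Whether a
  room is currently ahead of or behind its posted schedule is irrelevant
  to this rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import time
from typing import Sequence

from .errors import ValidationError
from .times import time_to_minutes


@dataclass(frozen=True)
class ServiceBookingState:
    """Allocated vs already-scheduled hours for one service."""

    service: str
    allocated_hours: float
    scheduled_hours: float

    def __post_init__(self) -> None:
        if self.allocated_hours < 0 or self.scheduled_hours < 0:
            raise ValidationError("allocated and scheduled hours must be nonnegative")

    @property
    def unscheduled_hours(self) -> float:
        return self.allocated_hours - self.scheduled_hours


@dataclass(frozen=True)
class ORDayState:
    """Projected vs allocated end of one OR's day."""

    or_name: str
    allocated_end: time
    projected_end: time
    behind_schedule_minutes: float = 0.0

    @property
    def over_utilized_hours(self) -> float:
        """Expected hours running past the allocated end (never negative)."""
        delta = time_to_minutes(self.projected_end) - time_to_minutes(self.allocated_end)
        return max(0.0, delta) / 60.0


def release_service(
    states: Sequence[ServiceBookingState],
) -> tuple[ServiceBookingState, float]:
    """Pick the service whose allocated OR time should be released.

    Returns the state with the largest allocated-minus-scheduled margin
    together with that margin in hours; exact ties go to the
    alphabetically first service, with a warning.
    """
    if not states:
        raise ValidationError("release_service requires at least one booking state")
    best_margin = max(s.unscheduled_hours for s in states)
    winners = sorted(
        (s for s in states if s.unscheduled_hours == best_margin),
        key=lambda s: s.service,
    )
    if len(winners) > 1:
        warnings.warn(
            f"release margin tie among {[s.service for s in winners]}; "
            "choosing alphabetically first",
            stacklevel=2,
        )
    return winners[0], best_margin


def prioritize_or(states: Sequence[ORDayState]) -> tuple[ORDayState, float]:
    """Pick the OR whose next patient should be prepared first.

    Returns the OR with the largest expected over-utilized time and that
    time in hours.  Behind/ahead-of-schedule status is ignored by design:
    starting the next case sooner in the most over-utilized OR removes
    the costliest hours.  Exact ties go to the alphabetically first OR
    name, with a warning.
    """
    if not states:
        raise ValidationError("prioritize_or requires at least one OR-day state")
    best = max(s.over_utilized_hours for s in states)
    winners = sorted(
        (s for s in states if s.over_utilized_hours == best), key=lambda s: s.or_name
    )
    if len(winners) > 1:
        warnings.warn(
            f"over-utilized-time tie among {[s.or_name for s in winners]}; "
            "choosing alphabetically first",
            stacklevel=2,
        )
    return winners[0], best
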