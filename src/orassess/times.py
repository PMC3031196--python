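"""Time-of-day helpers: grid rounding and clock-time formatting.

All parameter-derivation steps that produce a clock time snap it to a
staffing grid (15 minutes by default).  Two flavours are needed:

* nearest-grid rounding, for first-case start times (ties round up, so the
  result is deterministic), and
* round-up-to-grid, for workday end times (an exact grid point is left
  unchanged; one minute past it moves to the next grid point).
"""

from __future__ import annotations

from datetime import time

#: Monday-first weekday names, matching ``datetime.date.weekday()`` indices.
WEEKDAY_NAMES = (
    "Monday",
    "Tuesday",
    "Wednesday",
    "Thursday",
    "Friday",
    "Saturday",
    "Sunday",
)

#: Non-breaking space used between the numerals and the AM/PM designator in
#: rendered scenario text, so a line break can never separate them.
NBSP = " "


def time_to_minutes(t: time) -> float:
    """Clock time -> minutes after midnight (seconds kept as a fraction)."""
    return t.hour * 60 + t.minute + t.second / 60.0


def minutes_to_time(minutes: float) -> time:
    """Minutes after midnight -> clock time, truncated to whole minutes."""
    m = int(round(minutes))
    if not 0 <= m <= 24 * 60:
        raise ValueError(f"minutes out of range for a clock time: {minutes}")
    if m == 24 * 60:  # midnight at the end of the day
        m = 24 * 60 - 1
    return time(m // 60, m % 60)


def round_to_grid(t: time, grid_minutes: int) -> time:
    """Round to the nearest grid point; exact half-grid ties round up."""
    m = time_to_minutes(t)
    lower = (m // grid_minutes) * grid_minutes
    frac = m - lower
    snapped = lower if frac < grid_minutes / 2.0 else lower + grid_minutes
    return minutes_to_time(snapped)


def ceil_to_grid(t: time, grid_minutes: int) -> time:
    """Round up to the next grid point; an exact grid point is unchanged."""
    m = time_to_minutes(t)
    lower = (m // grid_minutes) * grid_minutes
    snapped = lower if m == lower else lower + grid_minutes
    return minutes_to_time(snapped)


def format_clock(t: time, nbsp: bool = True) -> str:
    """Render ``time(16, 15)`` as ``"4:15 PM"`` (non-breaking space by default)."""
    hour12 = t.hour % 12 or 12
    suffix = "AM" if t.hour < 12 else "PM"
    sep = NBSP if nbsp else " "
    return f"{hour12}:{t.minute:02d}{sep}{suffix}"


def parse_clock(text: str) -> time:
    """Parse ``"HH:MM"`` (24-hour) into a :class:`datetime.time`."""
    hh, mm = text.strip().split(":")
    return time(int(hh), int(mm))
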