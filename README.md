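# orassess

Automated needs assessment of operating-room (OR) management decision-making
from facility case-log data.

Surgical suites lose money in two asymmetric ways: staffed OR hours that go
unused (*under-utilized time*) and hours that run past the end of staffing
(*over-utilized time*, which costs more — a ratio of 1.5 is standard because
staff working late earn premium pay and want to go home). Many of the daily
decisions that drive this loss — which service's allocated time to release
for a new case, which patient to prepare next, whether to move a case — have
closed-form efficiency-maximizing answers, yet information systems never
record *why* a manager decided otherwise. `orassess` supports the
event-based knowledge-elicitation approach to this problem: it analyzes a
facility's case log, derives the facility's own operating parameters, adapts
a library of 45 hypothetical decision scenarios (19 chapters, from
definitions of OR efficiency through sequencing urgent cases) so that every
cue in the text — OR names, services, workday hours — matches the facility,
and assembles an indexed needs-assessment document that local managers can
page through in about an hour, flagging the scenarios where their practice
differs from the efficiency-maximizing decision.

The package is aimed at OR-management analysts and researchers in
perioperative operations; it also ships a seeded synthetic case-log
generator so the full pipeline is testable without confidential data.

## The model

For a service with daily elective workloads `w_d` (case-hours plus turnover
time, urgent cases excluded, turnovers capped at 90 min) and an allocation
of `A` staffed hours, the *inefficiency of use of OR time* is

    inefficiency(A) = Σ_d [ (A − w_d)⁺ + r · (w_d − A)⁺ ],   r = 1.5

in under-utilized-hour equivalents. The allocation chooses the number of
ORs `k` (each staffed `h` hours, default 8) minimizing `inefficiency(k·h)`
by direct search over `k = 0, 1, 2, …`. As the granularity `h` shrinks,
the optimum converges to the newsvendor solution, the `r/(1+r) = 0.60`
quantile of daily workload. Service/weekday pairs averaging under the
5.60-h break-even are pooled into the open, first-scheduled-first-served
OTHER pseudo-service. Analysis runs over the most recent nine four-week
periods, with holidays and slow-down days inferred from unusually low
weekday workloads and a rank-correlation trend test guarding the
stationarity assumption (a facility that fails it receives non-adapted
scenario text).

Scenario parameters are derived by deterministic rules: the two busiest ORs
by case count; the modal first-case start time (nearest 15 min) on
Thursdays; the workday end as the median time at which the number of
still-running ORs drops below 0.60 of that day's active rooms, rounded up
to the next 15 min; per-weekday median counts of first-case starts; and the
earliest weekday with at least three single-OR services.

## Worked example

```python
from orassess import ServiceBookingState, ORDayState, release_service, prioritize_or

# Three services, one 8-h OR each, with 9, 6, and 3 h of cases scheduled.
winner, margin = release_service([
    ServiceBookingState("General Surgery", 8.0, 9.0),
    ServiceBookingState("Orthopedics", 8.0, 6.0),
    ServiceBookingState("Pain Medicine", 8.0, 3.0),
])
print(winner.service, margin)   # Pain Medicine 5.0

# Two ORs allocated until 5:00 PM, projected to end 7:00 PM and 5:00 PM.
from datetime import time
or_, hours = prioritize_or([
    ORDayState("OR 1", time(17, 0), time(19, 0)),
    ORDayState("OR 13", time(17, 0), time(17, 0)),
])
print(or_.or_name, hours)       # OR 1 2.0
```

Pain Medicine has 5.0 h of allocated-but-unscheduled time — the most — so
its OR time is released for the new case; OR 1 carries 2.0 h of expected
over-utilized time, so preparing its next patient comes first even if it is
currently ahead of schedule.

The same rules run from the shell over a whole facility:

```sh
orassess simulate --seed 3 --out caselog.csv
orassess analyze  --caselog caselog.csv --out profile.json
orassess report   --caselog caselog.csv --out assessment.md
# -> wrote 41 scenario pages in 18 chapters to assessment.md
```

(Scenarios whose premise cannot occur at the facility — e.g. one built
around a service holding several ORs when no service does — are excluded,
and the table of contents is regenerated accordingly.)

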