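# Methods

This note records the quantitative procedures implemented by `orassess`,
the parameters that matter, the behaviour of the synthetic-data generator,
and the design choices made where the method as published leaves room.

## Input data and cleaning

A case log is a table with one row per case: OR name, scheduling service,
surgeon, patient room-entry and room-exit timestamps (ISO-8601, local
facility time), and an urgent flag. Validation is per row: a case whose
exit is not strictly after its entry, or that crosses midnight, is dropped
with a reported line number. Overnight cases are rejected outright because
every downstream statistic groups cases by calendar date; a facility with
material overnight elective activity would need a different day model. Two
cases overlapping in the same OR on the same date indicate a corrupted
export and abort the read rather than being silently repaired.

Analysis uses the most recent nine four-week periods (252 days), anchored
to the latest date in the data and counted backwards; each retained case
carries its period index 1–9. Nine periods is the method's published
operating point, chosen in the original line of work by training/testing
comparison; shorter logs are analyzed whole and flagged.

Holidays and slow-down days are not listed anywhere in a case log, so they
are inferred: a Monday–Friday date whose total case-hours fall below a
quarter (`holiday_fraction`, default 0.25) of the median case-hours of the
same weekday across the window is excluded from all statistics. The
fraction is this package's own operationalization of "very low workload";
0.25 cleanly separates true closures (at or near zero) from ordinary light
days, which rarely fall below half of the weekday median.

## Turnovers, workloads, allocation

Turnover time is the gap from one patient's exit to the next patient's
entry in the same OR on the same date. Gaps longer than 90 minutes are
scheduled delays rather than cleanup/setup and are capped at 90 minutes.
A turnover is attributed to the service of the *following* case — the gap
prepares the room for it; the attribution is symmetric in aggregate and
the choice is configurable in code.

The elective workload of a service on a date is the sum of its elective
case durations plus its attributed capped turnovers; urgent cases (and
turnovers leading into them) contribute nothing. Dates on which a service
did not operate count as zero-workload days, not missing data: the
allocation question is "how many ORs should be staffed for this service on
this weekday", and a day with no cases is informative demand.

For allocation, over-utilized time is costed at `cost_ratio` (1.5) times
under-utilized time, and the inefficiency of use of OR time for allocation
`A` over days `d` is `Σ (A − w_d)⁺ + 1.5 (w_d − A)⁺`, reported in
under-utilized-hour equivalents. Service/weekday pairs with mean workload
strictly below 5.60 h are pooled into OTHER (the break-even constant is
configured, not derived here). The number of ORs is chosen by evaluating
0, 1, 2, … ORs of `staffed_hours_per_or` (default 8 h — the method's
published tables do not state hours per staffed OR, so this is an explicit
package parameter) and keeping the smallest inefficiency, ties toward
fewer ORs to avoid gratuitous under-utilized time. The search is exact:
cost is piecewise linear and convex in `A`, so stopping once the
allocation exceeds the maximum daily workload by one staffed OR is safe,
and the unit tests cross-check against exhaustive enumeration. With fine
granularity the chosen hours converge on the 0.60 quantile of daily
workload (`cost_ratio/(1+cost_ratio)`), which the tests also verify.

Stationarity of workload over the window is tested by two-sided Spearman
rank correlation between period index (1–9) and per-period facility
workload totals, at `trend_alpha = 0.01`. The original reports defer the
exact test to earlier methodological work; rank correlation is assumption-
light and has the intended behaviour at both extremes (constant totals
pass; a strictly monotone sequence of nine totals fails). A failing
facility keeps its computed allocations but receives non-adapted scenario
text, since parameters derived from a drifting process would not describe
a stable operating state.

## Scenario parameters

All clock-time parameters snap to a 15-minute staffing grid. Two rounding
flavours are used and both are deterministic: first-case start times round
to the *nearest* grid point (half-grid ties up), workday end times round
*up* (an exact grid time is unchanged; one minute past it moves a full
step, so 4:00 PM stays 4:00 PM while 4:01 PM becomes 4:15 PM). Medians of
an even number of clock times take the earlier central value before
rounding; medians of counts take the lower central value so the result
stays integral.

Thursday is the reference weekday for time-of-day parameters because it is
a mid-workweek day in both Monday–Friday and Sunday–Thursday workweeks;
it is configurable.

* **Busiest ORs** — ranked by case count over the window, ties
  alphabetical. OR names lacking an "OR"/"rm" token are prefixed with
  "OR " so scenario text never names a bare room label.
* **Workday start** — elective Thursday cases entering 06:45–10:00,
  first case per OR per date, rounded starts tallied, modal value (ties to
  the earliest time).
* **Workday end** — per Thursday, with `m` ORs running elective cases,
  the earliest case-exit instant at which fewer than `0.60·m` ORs are
  still running; the median over Thursdays, rounded up. An OR counts as
  running until its **last** elective case of the date exits. The
  alternative — counting a room as idle whenever it is momentarily between
  cases — was implemented first and rejected: with realistic turnover
  gaps, several rooms are simultaneously between cases in mid-morning, the
  running count dips below threshold hours before any room has finished
  its day, and the derived "end of workday" lands around 09:00. The
  last-case definition matches the quantity the rule is after (when the
  suite empties for the day) and recovers the configured end time in
  simulation.
* **First-case counts** — all cases (urgent included, as the source
  procedure is written) entering 06:45–09:30, first per OR per date,
  counted per date, lower median per weekday.
* **Single-OR weekday** — the earliest weekday (Monday-first ordering)
  with at least three named services allocated exactly one OR; the first
  three alphabetically, plus the total ORs allocated to named services
  that weekday. When no weekday qualifies the parameter is absent and the
  scenario needing it is excluded rather than filled with fabricated
  values.

## Scenario library and document

The library holds 19 chapters with 45 scenarios (chapter counts
3,1,1,1,4,1,2,1,4,1,2,1,1,5,1,6,2,6,2). Two bodies are the published
worked examples (release of allocated time; day-of-surgery
prioritization), stored with placeholders `[S1]`…`[S9]` and rendered
through one of two binding schemes; the other 43 bodies are stand-ins
authored to their chapter topics and flagged `stand_in` in the manifest,
with metadata (counts, adaptability, applicability predicates) that the
loader integrity-checks on every load. Exactly two scenarios are
non-adaptable — they would require per-case anesthesia-provider types and
a procedure vocabulary, which case logs do not carry — and always render
with library-default values. Rendered times carry a non-breaking space
before AM/PM. Applicability predicates (`NEEDS_3_SINGLE_OR_SERVICES`,
`NEEDS_OTHER_EXACTLY_1_OR`, `NEEDS_PARTIAL_WEEK_SERVICE`,
`NEEDS_MULTI_OR_SERVICE`) exclude scenarios whose premise cannot occur at
the facility; the document's table of contents is generated from the
retained set, and retained scenarios are renumbered 1…k within each
chapter. Output is deterministic Markdown; PDF conversion is left to any
standard converter.

## Synthetic data

The generator emulates the structure the analysis assumes: per-service
per-weekday mean daily workloads with normal day-to-day noise (truncated
at zero), lognormal case durations (right-skewed, as OR durations are),
truncated-normal turnover gaps (which occasionally exceed 90 minutes and
exercise the cap), holiday dates with no activity, and urgent add-on
cases. Cases are packed into each service's OR from the configured first
start, appending a case only while doing so brings the realized workload
closer to the day's target, which keeps the realized mean unbiased up to
packing granularity. Urgent cases are generated *in addition to* the
elective target (each elective case spawns a trailing urgent case with
probability `urgent_fraction`) so that elective workload statistics
recover the configured means at any urgent load. The default facility has
five single-OR weekday services with means from 9 h down to 5 h, 30 ± 10
min turnovers, and 10% urgent load — sized like a small community suite
and deliberately spanning the pooling threshold.

What the generator does **not** emulate: add-on insertion and
cancellations during the day, surgeon-level OR affinity, seasonal trends,
weekend elective activity, or correlated workload across services.
Passing tests on synthetic logs therefore demonstrate correctness of the
computations under the stated statistical assumptions, not robustness to
every artefact of real AIMS exports.

Test problem sizes are chosen to make sampling error negligible relative
to the tolerances: workload-recovery runs one service over nine periods
(~180 workdays, tolerance 0.3 h ≈ 3·SD/√n), parameter recovery uses 20
seeded five-OR facilities (start recovered exactly; end within one
15-minute grid step), and the stationarity check's type-I rate is
estimated over 200 stationary draws against its 0.01 level.

## Known limitations

* The 5.60-h pooling break-even is a configured constant tied to the 1.5
  cost ratio and 8-h staffing; changing either without re-deriving the
  break-even makes the two inconsistent.
* Holiday inference needs several weeks of data per weekday before the
  median is stable; on very short logs it may flag nothing.
* The workday-end rule assumes most ORs start in the morning; a suite
  with a large planned evening shift would need a different definition.
* Stand-in scenario bodies are pedagogical placeholders: their metadata is
  authoritative for counting and applicability, their prose is not part of
  the validated method.
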