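A service generates enough workload for its own OR on two weekdays but books only scattered short cases on the others. The manager asks whether the service must receive the same allocation every day of the week.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

Allocation is decided separately for each combination of service and day of week. The service holds its own OR on the weekdays where that minimizes the inefficiency of use of OR time, and books into open OTHER time on the remaining days.
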