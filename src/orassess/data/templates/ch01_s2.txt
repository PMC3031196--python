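The nurse manager of [S1] calls in sick for tomorrow. The charge nurse asks whether tomorrow's OR allocation must be reduced by one room.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

Staff scheduling, not the allocation, absorbs day-to-day absences. The allocation was chosen from the services' workloads; the staffing office fills it by float pool, trade, or agency coverage. Reducing the allocation would convert a staffing problem into over-utilized OR time for every service scheduled tomorrow.
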