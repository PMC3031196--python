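In [S1], the surgeon following a morning case is not available until mid-afternoon, leaving a long planned gap in the schedule.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

The gap is a scheduled delay, not a turnover, and is excluded from turnover statistics. Operationally it is open time: a short case or an urgent add-on can be placed into it without delaying the scheduled afternoon start.
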