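A service allocated one 8 hr OR runs 9 hr of cases and turnovers. The manager asks how this day compares with one that finished an hour early.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

The day had 1 hr of over-utilized OR time. Because an over-utilized hour costs 1.5 times an under-utilized hour, this day's inefficiency of use of OR time exceeds that of a day finishing 1 hr early.
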