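A service is allocated one 8 hr OR and its cases and turnovers finish after 6 hr. The manager asks how the day is scored.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

The day had 2 hr of under-utilized OR time and no over-utilized time. The inefficiency of use of OR time equals those 2 hr multiplied by the cost of an under-utilized hour.
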