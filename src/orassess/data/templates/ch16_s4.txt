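Two cases of 2 hr and 5 hr must be placed; one OR has 6 hr unscheduled and another 3 hr.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

Placing the 5 hr case into the 6 hr opening and the 2 hr case into the 3 hr opening leaves both ORs within allocation. The reverse packing forces over-utilized time, so fit should be checked before booking order.
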