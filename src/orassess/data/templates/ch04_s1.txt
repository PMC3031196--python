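In [S1], one patient leaves the room and the next enters 40 minutes later. The same afternoon a 2 hr gap separates two cases of different surgeons, the second of whom was booked to start at a fixed hour.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

The 40-minute gap is a turnover: cleanup and setup between sequential patients. The 2 hr gap is a scheduled delay and is excluded from turnover statistics; for analysis, gaps longer than 90 minutes are capped at 90 minutes so that scheduled delays do not inflate apparent turnover time.
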