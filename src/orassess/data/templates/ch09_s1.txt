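On [S5], a service's daily elective workload including turnovers has averaged close to one staffed OR-day over the analysis window. The committee asks how many ORs to allocate.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

The inefficiency of use of OR time is evaluated for 0, 1, 2, ... allocated ORs and the count with the smallest value is chosen. With mean workload near one staffed OR-day, one OR minimizes inefficiency; the decision is recomputed separately for each weekday.
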