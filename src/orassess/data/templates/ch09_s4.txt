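To "balance utilization," a committee proposes moving one OR on one weekday from the service holding the most ORs to the service with the highest percentage utilization of its single OR.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

Percentage utilization is not the objective. Each service's allocation already minimizes its own inefficiency of use of OR time; transferring an OR to the higher-utilization service would add over-utilized hours there or under-utilized hours at the donor, increasing total inefficiency.
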