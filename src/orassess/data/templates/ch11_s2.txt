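A service pooled into OTHER on [S5] complains that it cannot plan because it holds no block.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

The service's mean daily workload on that weekday is below the 5.60 hr break-even point, so a dedicated OR would mostly sit under-utilized. Its cases are booked first-scheduled, first-served into OTHER time, and the pooling decision is recomputed as its workload grows.
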