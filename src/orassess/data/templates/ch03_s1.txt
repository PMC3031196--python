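A surgeon states that because her service was allocated OR time from [S3] to [S5], the service is entitled to schedule exactly those hours every week, no more and no less.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

Allocated OR time is a staffing plan computed from the service's historical workload, not an entitlement or a cap. The service schedules its cases as they arise; on days its workload exceeds the allocation its cases still run, in over-utilized time.
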