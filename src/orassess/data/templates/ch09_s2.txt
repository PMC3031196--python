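A committee proposes allocating each service its mean daily workload rounded to the nearest whole OR.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

Rounding the mean ignores that an over-utilized hour costs 1.5 times an under-utilized one. The efficiency-maximizing allocation covers the 60th percentile of the daily workload distribution, so services with variable workload receive more than their rounded mean.
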