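A surgeon requests guaranteed block time every [S5] equal to her personal average caseload, separate from her service's allocation.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

OR time is allocated to services, not surgeons, because the service's pooled daily workload has less relative variability than any one surgeon's. Surgeon-specific blocks inside the service's ORs would increase expected under- and over-utilized time for the same total staffed hours.
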