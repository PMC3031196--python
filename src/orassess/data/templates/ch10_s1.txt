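A newly recruited surgeon has no case history at the facility. The committee must decide her service's allocation for next quarter.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

Historical workload cannot inform a brand-new program, so qualitative planning data - contracted caseload, referral projections - justify an initial allocation. The exception should be explicit and time-limited, with the allocation recomputed from actual workload as soon as the analysis window fills.
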