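A service holding more than one allocated OR on its busiest weekday asks that the rooms be converted into surgeon-specific blocks of equal size.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

Allocations are computed by service, not by surgeon, because the service's combined daily workload is what determines the inefficiency of use of OR time. Equal surgeon-specific blocks within the service's ORs would not change the allocation, but managing to them instead of to the service total increases over-utilized time.
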