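On one weekday the pooled low-workload services together justify exactly one OR of open, unblocked OTHER time. A manager proposes splitting that single OR into fixed morning and afternoon blocks promised to two of the pooled services.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

The OTHER OR should remain first-scheduled, first-served. Splitting one OR into promised blocks recreates the low-workload allocations that pooling was designed to eliminate and increases expected under-utilized time.
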