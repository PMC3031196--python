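A service with its allocated OR time fully scheduled asks to add a 2 hr case. Two other services have unscheduled allocated time remaining.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

The case is placed into the time of the service with the most allocated but unscheduled OR time, because that service is expected to have the most under-utilized time on the day of surgery. The releasing service keeps booking its own cases as they arise.
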