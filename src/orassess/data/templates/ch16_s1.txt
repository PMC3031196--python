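A service wants to schedule a 4 hr case. Its own allocated time on the requested day has 5 hr unscheduled.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

The case goes into the service's own allocated time. Scheduling into another service's time or into OTHER time, while the service's own allocation stands unscheduled, would add expected under-utilized time in its own OR and over-utilized time elsewhere.
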