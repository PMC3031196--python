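A 7 hr case is proposed for an OR whose remaining allocated time on that day is 5 hr, while another weekday has a fully open allocation for the service.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

Scheduling the long case into 5 remaining hours guarantees at least 2 hr of over-utilized time. Offering the open weekday first respects access while avoiding predictable over-utilized hours.
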