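Allocated OR time at the facility runs from [S3] to [S5]. An anesthesiologist asks why the posted staff schedule shows some teams until [S4].

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

Part of the staff is deliberately scheduled past the end of allocated OR time because some workload lands in over-utilized hours even under the efficiency-maximizing allocation. Planning a late team is cheaper than unplanned overtime across many teams.
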