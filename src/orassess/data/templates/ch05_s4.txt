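A manager proposes judging each weekday by the percentage utilization of allocated time, targeting 85%.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

Percentage utilization hides the asymmetry that makes over-utilized time costlier than under-utilized time and can be raised by deliberately under-allocating. OR efficiency is the value maximized when the inefficiency of use of OR time is minimized, and allocations should be judged by that criterion.
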