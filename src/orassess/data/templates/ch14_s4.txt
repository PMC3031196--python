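A manager declines to release another service's time for a 1 hr case, reasoning that releases are only worthwhile for long cases.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

Choosing the service with the most allocated but unscheduled OR time matters most for long cases, where a wrong choice causes hours of over-utilized time. For a short case the expected difference is small, and a reasonable compromise placement is acceptable.
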