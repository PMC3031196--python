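A service is allocated two ORs on its busiest weekday. Its chief notes that on many such days one of the two rooms finishes early and asks that the second OR be withdrawn.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

The allocation of two ORs minimizes the inefficiency of use of OR time given the whole distribution of the service's daily workload: the cost of over-utilized hours on heavy days outweighs the under-utilized hours on light ones at the 1.5 cost ratio. Withdrawing the OR because of light days alone would raise expected inefficiency.
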