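Two ORs are allocated 8 hr each. One finishes in exactly 8 hr; the other runs 10 hr.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

The first OR contributes nothing to the inefficiency of use of OR time. The second contributes 2 hr of over-utilized time at the higher cost rate; total inefficiency is 2 hr multiplied by 1.5, i.e. 3.0 under-utilized-hour equivalents.
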