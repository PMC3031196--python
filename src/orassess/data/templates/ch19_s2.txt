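A surgeon insists his urgent case precede another service's urgent case because his was posted first.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

Sequence follows medical urgency first; among equally urgent cases, the order minimizing expected over-utilized OR time is preferred. Posting order is a tie-break of last resort, not the rule.
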