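A surgeon asks to book a case on a day when her service's allocation is full, rather than accept an open day later the same week.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

Access means the service can always book a case on some workday, not any workday. When the requested day is full, offering the open day first avoids scheduled over-utilized time; only a clinical reason to operate sooner justifies the full day.
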