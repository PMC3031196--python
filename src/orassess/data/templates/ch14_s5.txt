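Surgeons in the service whose OR time was just released for another service's case protest that they have lost access.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

Releasing allocated OR time is not a loss of access: the releasing service's surgeons continue to book cases, which are scheduled into remaining open time. The release only places one known case where the most under-utilized time is expected.
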