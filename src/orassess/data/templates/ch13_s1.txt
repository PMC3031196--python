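Next year's OR staffing budget is being drafted from last year's overtime charges.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

The budget should instead be built from the efficiency-maximizing allocations: staffed hours at straight time for each allocated OR plus expected over-utilized hours at premium rates. Budgeting from past charges locks in whatever inefficiency produced them.
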