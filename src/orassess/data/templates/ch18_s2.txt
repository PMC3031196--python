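At [S3], every OR has started on time. The charge nurse asks what single number to watch during the day.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

The expected over-utilized OR time in each room. On the day of surgery the allocation is fixed, so efficiency is influenced only through decisions - calling for patients, moving cases, assigning relief - that reduce expected over-utilized time.
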