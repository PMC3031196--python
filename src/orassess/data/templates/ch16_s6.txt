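At [S3] the schedule for [S1] shows its last case ending well before [S5], and a compatible add-on case is waiting.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

Scheduling the add-on into [S1] fills expected under-utilized time without creating over-utilized time, increasing OR efficiency. The add-on should be placed there rather than extending a room already projected to run past its allocated end.
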