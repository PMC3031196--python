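At [S3] the board shows every room projected to finish before [S5]. A manager proposes sending a team home early from the room that started first.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

With no expected over-utilized time, early releases are a staffing decision, not an efficiency one; they should follow the posted relief order. The efficiency criterion only constrains decisions that would create over-utilized time.
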