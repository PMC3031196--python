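An OR is running 30 minutes behind its posted schedule but is still projected to finish before the end of allocated time at [S5]. The surgeon asks the desk to expedite everything for that room.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

Being behind the posted schedule without expected over-utilized time calls for no special action on efficiency grounds. Reducing that room's tardiness ranks below reducing over-utilized time elsewhere, under the fourth priority of reducing patient waiting.
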