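Two ORs each have one case remaining. One is projected to finish at its allocated end of [S5]; the other at [S4]. Only one post-anesthesia care bed is open.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

The bed is held for the room projected to finish at [S4], the one generating over-utilized time. Delaying that room's exit for lack of a bed extends the most expensive hours of the day.
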