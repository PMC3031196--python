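A charge nurse proposes moving a case between two ORs that are both projected to finish within their allocated time, to make the board look balanced.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

Neither room is expected to have over-utilized time, so the move cannot increase OR efficiency. It adds handoff and setup risk for no benefit and should not be made.
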