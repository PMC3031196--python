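Two urgent cases of equal medical urgency are waiting; one OR is projected to finish 2 hr before [S5] and another right at [S5].

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

Both cases being equally urgent, the first goes to the OR projected to finish 2 hr early: filling expected under-utilized time defers no care and avoids pushing the other room into over-utilized hours.
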