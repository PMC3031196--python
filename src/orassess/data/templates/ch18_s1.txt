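At 12 noon, both [S1] and [S2] expect to be ready for their next patient in 45 minutes. Preparing each of the patients for surgery will take approximately the same amount of time.

Allocated OR time is from [S3] to [S5]. [S1] is ahead of schedule by 30 minutes. [S2] is behind schedule by 30 minutes. [S1] is scheduled to end its cases at [S4]. [S2] is scheduled to end its cases at [S5].

Preparing which of the two patients should be a higher priority?

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

Maximizing OR efficiency (i.e., minimizing over-utilized OR time) is a higher-priority than reducing patient waiting from scheduled start times. Therefore, preparing the patient for [S1] is a higher priority than for [S2], even though [S2] is behind schedule.
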