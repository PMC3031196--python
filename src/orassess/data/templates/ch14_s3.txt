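The scheduling office releases every service's unscheduled allocated time a fixed 10 working days before each date of surgery.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

Services fill their allocated time at very different rates, so one fixed horizon releases some services' time too early and others' too late. Release decisions should be made case by case, choosing the service with the most allocated but unscheduled OR time when a new case needs a room.
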