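At 10 AM a surgeon asks that an inpatient be added to today's list, stating the case is urgent. The schedulers' written definitions distinguish elective cases, which can be scheduled for a future workday, from urgent cases, which must be done sooner for medical reasons.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

Whether the case is urgent is a clinical determination made against the facility's written definition, not a scheduling convenience. Urgent cases are excluded from the elective workload statistics used for OR allocation, so consistent classification protects the integrity of every downstream staffing decision.
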