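After a quarter with rising caseload, the perioperative director reports falling labor productivity and proposes asking teams to work faster.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

Labor productivity is case-hours performed per staffed OR hour paid. When it falls while caseload rises, the usual cause is allocations no longer matching workload by service and weekday. Reallocating ORs recovers productivity; exhorting teams does not.
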