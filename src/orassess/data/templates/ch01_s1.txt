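An academic suite staffs its ORs with anesthesiologists medically directing residents and nurse anesthetists. The OR manager is asked whether assignment of providers to rooms, the monthly staff schedule, and the allocated OR time for each service are three names for the same plan.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

They are distinct decisions made on different time scales. Allocated OR time is the planned hours for each service and weekday, chosen to maximize OR efficiency; staff scheduling fills those hours months ahead; assignment matches individual providers to rooms on the day itself. Conflating them leads to staffing being treated as fixed when allocations should change.
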