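A scheduler offers a surgeon the first available slot in any OR, two days ahead, although the surgeon's service has unscheduled allocated time later in the week.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

First-available scheduling maximizes neither access nor efficiency: it fills other services' time while the service's own allocation goes under-utilized. The case should be scheduled into the service's own allocated time unless the patient's condition requires an earlier date.
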