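Among the [S6] ORs typically started on [S5], there are [S1] ORs allocated to specific services. The services "[S2]," "[S3]," and "[S4]" have each been allocated one OR. [S2] has scheduled 9 hr of cases in its OR. [S3] has 6 hr of cases scheduled into its OR. Surgeons in [S4] have scheduled a 3 hr case. The remaining ORs are fully booked. [S2] wants to schedule another case.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

[S2] can book the case, because it has access to OR time on whatever work day the service chooses. If based on surgeon availability, staff knowledge, equipment availability, etc., the case can be performed safely in the OR time allocated for [S4], then [S4] would have its OR time released for the [S2] case. This is because [S4] has the largest difference between the allocated and scheduled hours of cases (i.e., would be expected to have the most under-utilized OR time on the day of surgery).
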