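The finance office asks how many hours of under-utilized OR time to expect next quarter under the current allocations.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

Expected under-utilized time is estimated per service and weekday as the average positive difference between allocated hours and the distribution of daily workload, then summed. It is a property of the allocation against workload variability, not a measure of team idleness.
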