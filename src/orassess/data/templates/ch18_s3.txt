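At 3 PM, [S1] is projected to end at [S4], after the end of allocated OR time at [S5]. The relief team can be sent to any room.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

Relief goes to [S1]: keeping its team working without breaks shortens the room's remaining time and reduces the over-utilized hours, which cost more than any equal-length reduction in a room finishing within allocation.
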