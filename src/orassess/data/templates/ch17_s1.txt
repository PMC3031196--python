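At midday, [S1] is projected to run 2 hr past the end of allocated OR time while another OR of the same service is projected to finish 2 hr early. The waiting case can be done safely in either room.

OR management, staffing, and case scheduling decisions are made based on four ordered priorities: Safety, Access, OR efficiency, and Reducing patient waiting on the day of surgery.

Moving the case into the early-finishing OR reduces expected over-utilized time by up to 2 hr at no cost in safety or access, so the move should be made.
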