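# References

1. McIntosh C, Dexter F, Epstein RH. The impact of service-specific staffing, case
   scheduling, turnovers, and first-case starts on anesthesia group and operating
   room productivity: a tutorial using data from an Australian hospital.
   Anesth Analg 2006;103:1499-516.
2. Strum DP, Vargas LG, May JH. Surgical subspecialty block utilization and
   capacity planning: a minimal cost analysis model. Anesthesiology 1999;90:1176-85.
3. Dexter F, Traub RD. How to schedule elective surgical cases into specific
   operating rooms to maximize the efficiency of use of operating room time.
   Anesth Analg 2002;94:933-42.
4. Dexter F, Epstein RH, Marcon E, Ledolter J. Estimating the incidence of
   prolonged turnover times and delays by time of day. Anesthesiology
   2005;102:1242-8.
5. Dexter F, Epstein RH, Traub RD, Xiao Y. Making management decisions on the day
   of surgery based on operating room efficiency and patient waiting times.
   Anesthesiology 2004;101:1444-53.
6. Pandit JJ, Dexter F. Lack of sensitivity of staffing for 8-hour sessions to
   standard deviation in daily actual hours of operating room time used for
   surgeons with long queues. Anesth Analg 2009;108:1910-5.
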