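scenario,frac_cs,frac_noac,hospital_inr_visits,nurse_hours,doctor_hours
Baseline,0.0,0.0,60463,9504,4199
Scenario 1,0.1,0.1,52112,8618,3819
Scenario 2,0.1,0.2,44615,7537,3356
Scenario 3,0.1,0.4,35644,5889,2650
Scenario 4,0.1,0.5,28330,5041,2286
Scenario 5,0.2,0.1,48041,8465,3754
Scenario 6,0.2,0.2,41312,7446,3317
Scenario 7,0.2,0.4,33268,5941,2672
Scenario 8,0.2,0.5,27644,5021,2278
Scenario 9,0.4,0.1,41376,8050,3576
Scenario 10,0.4,0.2,35694,7154,3192
Scenario 11,0.4,0.4,30423,5961,2681
Scenario 12,0.4,0.5,25754,5106,2314
Scenario 13,0.5,0.1,39711,7944,3530
Scenario 14,0.5,0.2,34140,6999,3126
Scenario 15,0.5,0.4,29114,5884,2648
Scenario 16,0.5,0.5,24793,5008,2272
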