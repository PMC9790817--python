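scenario,frac_cs,frac_noac,NOAC_community,standard_community,NOAC_hospital,standard_hospital
Scenario 1,0.1,0.1,336.4,66.1,111.2,25.0
Scenario 2,0.1,0.2,251.4,64.7,115.1,25.5
Scenario 3,0.1,0.4,194.1,68.9,121.1,25.1
Scenario 4,0.1,0.5,174.2,65.7,119.2,25.2
Scenario 5,0.2,0.1,295.7,64.6,103.9,25.0
Scenario 6,0.2,0.2,237.1,64.2,112.7,25.9
Scenario 7,0.2,0.4,186.0,67.1,121.3,25.1
Scenario 8,0.2,0.5,176.7,68.3,121.3,25.5
Scenario 9,0.4,0.1,258.1,66.2,89.0,25.0
Scenario 10,0.4,0.2,219.2,68.0,106.2,25.4
Scenario 11,0.4,0.4,189.8,68.5,119.6,24.7
Scenario 12,0.4,0.5,185.4,69.4,120.1,25.3
Scenario 13,0.5,0.1,236.5,64.3,86.1,25.2
Scenario 14,0.5,0.2,207.4,66.9,105.5,25.7
Scenario 15,0.5,0.4,184.8,67.2,121.1,25.0
Scenario 16,0.5,0.5,182.5,68.0,121.1,26.3
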