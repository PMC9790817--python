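scenario,frac_cs,frac_noac,standard_care_cost,noac_cost,staff_cost,total_cost
Baseline,0.0,0.0,2811048,0,1774893,4585941
Scenario 1,0.1,0.1,2398573,116898,1613095,4128567
Scenario 2,0.1,0.2,2054464,224410,1415775,3694649
Scenario 3,0.1,0.4,1553305,403630,1114937,3071872
Scenario 4,0.1,0.5,1262138,505103,960037,2727278
Scenario 5,0.2,0.1,2212853,125184,1585241,3923278
Scenario 6,0.2,0.2,1898084,217774,1399161,3515018
Scenario 7,0.2,0.4,1452477,387149,1124391,2964016
Scenario 8,0.2,0.5,1175053,483188,956465,2614699
Scenario 9,0.4,0.1,1831531,143566,1509454,3484551
Scenario 10,0.4,0.2,1580015,227182,1345870,3153067
Scenario 11,0.4,0.4,1242852,359149,1128102,2730103
Scenario 12,0.4,0.5,1018522,438128,971924,2428574
Scenario 13,0.5,0.1,1666528,153471,1490022,3310021
Scenario 14,0.5,0.2,1428968,231599,1317754,2978321
Scenario 15,0.5,0.4,1128107,352167,1114044,2594319
Scenario 16,0.5,0.5,915767,425174,954032,2294973
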