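sex,age_min,age_max,status,kcal_per_day,reference
f,0,2,none,800,0
m,0,2,none,850,0
f,3,9,none,1350,0
m,3,9,none,1450,0
f,10,17,none,2000,0
m,10,17,none,2400,0
f,18,29,none,2100,1
m,18,29,none,2600,0
f,30,59,none,2050,0
m,30,59,none,2500,0
f,60,120,none,1850,0
m,60,120,none,2100,0
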