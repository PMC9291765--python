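nutrient,har_units_per_day,unit,hul_units_per_day,density_classifiable,bioavailability_tier
vita_rae_ug,490,ug RAE,3000,1,
thiamine_mg,0.9,mg,,1,
riboflavin_mg,1.3,mg,,1,
niacin_mg,11,mg,,1,
vitb6_mg,1.1,mg,,1,
folate_ug,250,ug,,1,
vitb12_ug,2.0,ug,,1,
iron_mg,22.4,mg,,0,
zinc_mg,10.2,mg,,1,low
zinc_mg,8.9,mg,,1,moderate
zinc_mg,7.5,mg,,1,high
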