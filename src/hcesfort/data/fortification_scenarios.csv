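scenario,vehicle_item,nutrient,content_per_100g
no_fortification,oil,vita_rae_ug,0
status_quo,oil,vita_rae_ug,1000
improved_compliance,oil,vita_rae_ug,2100
no_fortification,sugar,vita_rae_ug,0
status_quo,sugar,vita_rae_ug,700
improved_compliance,sugar,vita_rae_ug,1050
no_fortification,wheat_flour,vita_rae_ug,0
status_quo,wheat_flour,vita_rae_ug,80
improved_compliance,wheat_flour,vita_rae_ug,180
no_fortification,wheat_flour,thiamine_mg,0.2
status_quo,wheat_flour,thiamine_mg,0.5
improved_compliance,wheat_flour,thiamine_mg,0.8
no_fortification,wheat_flour,riboflavin_mg,0.1
status_quo,wheat_flour,riboflavin_mg,0.3
improved_compliance,wheat_flour,riboflavin_mg,0.5
no_fortification,wheat_flour,niacin_mg,2.4
status_quo,wheat_flour,niacin_mg,4.2
improved_compliance,wheat_flour,niacin_mg,6.5
no_fortification,wheat_flour,vitb6_mg,0.5
status_quo,wheat_flour,vitb6_mg,0.7
improved_compliance,wheat_flour,vitb6_mg,0.9
no_fortification,wheat_flour,folate_ug,240
status_quo,wheat_flour,folate_ug,427
improved_compliance,wheat_flour,folate_ug,648
no_fortification,wheat_flour,vitb12_ug,0
status_quo,wheat_flour,vitb12_ug,0.6
improved_compliance,wheat_flour,vitb12_ug,1.3
no_fortification,wheat_flour,iron_mg,2.0
status_quo,wheat_flour,iron_mg,3.0
improved_compliance,wheat_flour,iron_mg,6.0
no_fortification,wheat_flour,zinc_mg,0.5
status_quo,wheat_flour,zinc_mg,1.8
improved_compliance,wheat_flour,zinc_mg,3.5
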