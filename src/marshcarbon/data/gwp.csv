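gas,report,horizon_years,value,uncertainty
CO2,AR4,100,1,
CO2,AR5,100,1,
CO2,AR6,100,1,
CO2,AR4,20,1,
CO2,AR5,20,1,
CO2,AR6,20,1,
CH4_nonfossil,AR4,100,25,
CH4_nonfossil,AR5,100,28,
CH4_nonfossil,AR6,100,27.2,11
CH4_nonfossil,AR4,20,21,
CH4_nonfossil,AR5,20,84,
CH4_nonfossil,AR6,20,80.8,25.8
N2O,AR4,100,298,
N2O,AR5,100,265,
N2O,AR6,100,273,130
N2O,AR4,20,310,
N2O,AR5,20,264,
N2O,AR6,20,273,118
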