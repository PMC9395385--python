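temperature_c,pressure_mpa,component,density_e3_g_ml
65,25,water,991.17
65,25,ethanol,773.97
65,25,ethanol_water_70,815.53
65,25,ethanol_water_80,795.68
65,25,ethanol_water_90,789.11
65,21,water,989.51
65,21,ethanol,770.51
65,21,ethanol_water_70,812.59
65,21,ethanol_water_80,780.99
65,21,ethanol_water_90,783.22
65,17,water,987.83
65,17,ethanol,766.77
65,17,ethanol_water_70,809.48
65,17,ethanol_water_80,789.13
65,17,ethanol_water_90,779.69
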