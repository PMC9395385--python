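# Component property sheets for the co-solvent system.
# Antoine constants: log10(P[mmHg]) = A - B/(C + T[degC]).
# Densities are 20 degC handbook values used for the %v/v -> mole-fraction
# conversion (high-pressure densities live in densities.csv).

[components.ethanol]
boiling_point_c = 78.37
flash_point_c = 13.0
antoine = [8.20417, 1642.89, 230.300]
hansen_delta = 26.5
density_g_ml = 0.789
molar_mass = 46.07
tlv_stel_ppm = 1000.0
nfpa_reactivity = 0
lel_vol_pct = 3.3
uel_vol_pct = 19.0

[components.water]
boiling_point_c = 100.0
antoine = [8.07131, 1730.63, 233.426]
hansen_delta = 47.8
density_g_ml = 0.998
molar_mass = 18.015
nfpa_reactivity = 0

# van Laar binary constants, ethanol(1)-water(2), standard VLE compilations
[activity.van_laar]
a12 = 1.6798
a21 = 0.9227
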