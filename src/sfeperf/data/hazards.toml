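# Qualitative hazard register for the SFE unit: per-equipment risks and the
# secondary scenarios that can follow a BLEVE. Descriptive data only; the
# quantitative scoring covers the co-solvent chemistry.

[[equipment]]
name = "co2_storage_tank"
risks = ["BLEVE"]
hazard_types = ["chemical", "thermodynamic", "biological"]

[[equipment]]
name = "co2_pump"
risks = ["overpressure"]
hazard_types = ["chemical", "biological"]

[[equipment]]
name = "cosolvent_pump"
risks = ["overpressure"]
hazard_types = ["chemical"]

[[equipment]]
name = "pressure_vessel"
risks = ["BLEVE", "overpressure"]
hazard_types = ["chemical", "thermodynamic", "mechanical"]

[[bleve_scenarios]]
main_scenario = "BLEVE"
vector = "overpressure"
secondary = [
  "flash fire", "pool fire", "jet fire", "fire ball",
  "vapour cloud explosion", "BLEVE", "toxic release",
]
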