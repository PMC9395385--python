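# Operational-cost configuration: prices, consumption and duty cycle.
# Monetary unit RM; tariff in sen/kWh (divided by 100 at compute time).
sample_price_rm_per_kg = 70.0
ethanol_price_rm_per_bottle = 86.0
bottle_volume_l = 2.5
co2_price_rm_per_cylinder = 224.0
cylinder_mass_kg = 30.0
electricity_tariff_sen_per_kwh = 36.5
labour_salary_rm_per_month = 1800.0
n_operators = 1
annual_hours = 8760.0
run_duration_h = 8.0
sample_mass_kg = 0.003
co2_mass_kg = 2.0
cosolvent_volume_l = 0.06
water_pct_vv = 20.0

[equipment_power_kw]
chiller = 13.82
co2_pump = 0.9
cosolvent_pump = 0.4
bpr = 0.5
oven = 0.8
ambient = 0.9
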