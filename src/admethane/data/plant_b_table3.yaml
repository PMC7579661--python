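# WARNING: alternate autoconsumption set for plant B, from the published
# model-input table.  Its thermal figure (845 MWh/y) and electricity
# figures (114 / 109.32 MWh/y) are inconsistent with the published GHG
# output rows (which imply 262 and 44.5 + 33.7 MWh/y); plant_b.yaml is
# canonical.  Kept for sensitivity comparison.
name: plant_b_table3
route: biomethane
annual_substrate_mass:
  pellets: 766
  green_coffee_powder: 155
  roasted_coffee_powder: 627
b0_mix: 0.27
annual_methane_nm3: 226000
biogas_t_per_day: 0.78
gross_biogas_energy_mwh: 1173.6
fugitive_biogas_kg_per_day: 2.3
ch4_loss_frac: 0.016
upgrading_efficiency: 0.986
thermal_autoconsumption_mwh: 845
electricity_autoconsumption_biogas_mwh: 114
electricity_autoconsumption_upgrading_mwh: 109.32
handling_fugitive_emissions_tco2e: 43.4
ef_natural_gas: 206
ef_electricity: 337
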