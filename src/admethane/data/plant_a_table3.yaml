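# WARNING: alternate autoconsumption set for plant A, from the published
# model-input table.  These values do not arithmetically reproduce the
# published GHG output rows; plant_a.yaml (the flow-description values) is
# canonical.  Kept for sensitivity comparison.
name: plant_a_table3
route: biomethane
annual_substrate_mass:
  pellets: 780
  green_coffee_powder: 70
  roasted_coffee_powder: 280
b0_mix: 0.24
annual_methane_nm3: 150000
biogas_t_per_day: 0.55
gross_biogas_energy_mwh: 830.4
fugitive_biogas_kg_per_day: 1.7
ch4_loss_frac: 0.016
upgrading_efficiency: 0.986
thermal_autoconsumption_mwh: 181
electricity_autoconsumption_biogas_mwh: 30.2
electricity_autoconsumption_upgrading_mwh: 22.9
handling_fugitive_emissions_tco2e: 30.7
ef_natural_gas: 206
ef_electricity: 337
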