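# Reference biomethane scenario, plant B (canonical parameter set).
name: plant_b
route: biomethane
annual_substrate_mass:
  pellets: 766
  green_coffee_powder: 155
  roasted_coffee_powder: 627
mix:
  name: plant_b
  basis: vs_mass
  components:
    green_coffee_powder: 0.092
    roasted_coffee_powder: 0.429
    pellets: 0.479
b0_mix: 0.27
annual_methane_nm3: 226000
biogas_t_per_day: 0.78
gross_biogas_energy_mwh: 1173.6
fugitive_biogas_kg_per_day: 2.3
ch4_loss_frac: 0.016
upgrading_efficiency: 0.986
thermal_autoconsumption_mwh: 262
electricity_autoconsumption_biogas_mwh: 44.5
electricity_autoconsumption_upgrading_mwh: 33.7
handling_fugitive_emissions_tco2e: 43.4
ef_natural_gas: 206
ef_electricity: 337
chp_electrical_efficiency: 0.40
chp_availability_h: 8000
ch4_vol_frac_biogas: 0.50
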