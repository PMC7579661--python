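# Reference biomethane scenario, plant A (canonical parameter set).
# Production anchors (annual methane, daily biogas mass, gross biogas
# energy) are independent inputs from different sub-models; see the
# plant module docstring.
name: plant_a
route: biomethane
annual_substrate_mass:
  pellets: 780
  green_coffee_powder: 70
  roasted_coffee_powder: 280
mix:
  name: plant_a
  basis: vs_mass
  components:
    green_coffee_powder: 0.062
    roasted_coffee_powder: 0.263
    pellets: 0.675
b0_mix: 0.24
annual_methane_nm3: 150000
biogas_t_per_day: 0.55
gross_biogas_energy_mwh: 830.4
fugitive_biogas_kg_per_day: 1.7
ch4_loss_frac: 0.016
upgrading_efficiency: 0.986
thermal_autoconsumption_mwh: 186
electricity_autoconsumption_biogas_mwh: 31.5
electricity_autoconsumption_upgrading_mwh: 23.9
handling_fugitive_emissions_tco2e: 30.7
ef_natural_gas: 206
ef_electricity: 337
chp_electrical_efficiency: 0.40
chp_availability_h: 8000
ch4_vol_frac_biogas: 0.50
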