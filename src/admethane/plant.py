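"""Full-scale valorization balances: CHP sizing and biomethane accounting.

Given a plant scenario (substrate tonnages, methane yield, conversion route
and the efficiency / autoconsumption / emission-factor set), this module
computes:

* CHP route: annual electricity from methane combustion in reciprocating
  engines and the engine power rating;
* biomethane route: daily mass flows (biogas, fugitive losses, upgraded
  biomethane, off-gas methane slip), annual energy flows (gross biogas
  energy, net energy in biomethane, external thermal/electric demands) and
  the greenhouse-gas balance (produced emissions vs. avoided emissions from
  natural-gas substitution).

Three printed production chains - annual methane volume, daily biogas mass
and gross biogas energy - are deliberately independent scenario inputs
rather than being rederived from one another: at preliminary-assessment
scale they come from different sub-models with their own defaults and are
not mutually consistent to the last digit.  Each balance uses the input
closest to it.

Sign convention: produced emissions are >= 0, avoided emissions <= 0, and
the balance is their plain sum.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

from .substrates import DAYS_PER_YEAR, MixSpec

__all__ = [
    "PlantScenario",
    "MassBalance",
    "EnergyBalance",
    "GHGBalance",
    "PlantReport",
    "methane_from_substrates",
    "chp_balance",
    "biomethane_mass_balance",
    "biomethane_energy_balance",
    "ghg_balance",
    "run_scenario",
    "round_half_away",
]

#: Lower heating value of methane, kWh per Nm3 (0 degC, 1e5 Pa).
METHANE_LHV_KWH_NM3 = 9.97
#: Gas densities at normal conditions, kg/Nm3.
METHANE_DENSITY = 0.716
CO2_DENSITY = 1.977


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (report formatting only, never internal)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class PlantScenario:
    """Full-scale scenario configuration.

    Production anchors (independent, see module docstring):

    annual_methane_nm3 : direct annual methane volume (default pathway)
    b0_mix : specific methane yield of the blend, Nm3/kg VS - used with the
        substrate VS tonnages when ``annual_methane_nm3`` is not given
    biogas_t_per_day : daily biogas mass for the upgrading mass balance
    gross_biogas_energy_mwh : annual biogas energy for the energy balance
    """

    name: str
    route: str = "biomethane"  # or "chp"
    annual_substrate_mass: Mapping[str, float] = field(default_factory=dict)  # t/y wet
    annual_vs_mass: Mapping[str, float] = field(default_factory=dict)  # t VS/y
    mix: MixSpec | None = None
    b0_mix: float | None = None            # Nm3 CH4 / kg VS
    annual_methane_nm3: float | None = None
    biogas_t_per_day: float | None = None
    gross_biogas_energy_mwh: float | None = None
    # conversion parameters
    chp_electrical_efficiency: float = 0.40
    chp_availability_h: float = 8000.0
    chp_heat_recovered_mwh: float = 0.0
    ch4_loss_frac: float = 0.016
    upgrading_efficiency: float = 0.986
    fugitive_biogas_kg_per_day: float | None = None
    # autoconsumptions (annual, external supply)
    thermal_autoconsumption_mwh: float = 0.0
    electricity_autoconsumption_biogas_mwh: float = 0.0
    electricity_autoconsumption_upgrading_mwh: float = 0.0
    # handling + fugitive CH4 GHG term, t CO2e/y (upstream model default)
    handling_fugitive_emissions_tco2e: float = 0.0
    # emission factors, g CO2e/kWh
    ef_natural_gas: float = 206.0
    ef_electricity: float = 337.0
    # gas properties
    methane_lhv_vol: float = METHANE_LHV_KWH_NM3   # kWh/Nm3
    methane_density: float = METHANE_DENSITY       # kg/Nm3
    co2_density: float = CO2_DENSITY               # kg/Nm3
    ch4_vol_frac_biogas: float = 0.50

    def __post_init__(self) -> None:
        if self.route not in ("chp", "biomethane"):
            raise ValueError(f"unknown route {self.route!r} (chp|biomethane)")
        for attr in (
            "chp_electrical_efficiency", "ch4_loss_frac",
            "upgrading_efficiency", "ch4_vol_frac_biogas",
        ):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr}={v} outside [0, 1]")
        if not 0.0 <= self.chp_availability_h <= 8760.0:
            raise ValueError("chp_availability_h must lie in [0, 8760]")
        if self.ef_natural_gas < 0 or self.ef_electricity < 0:
            raise ValueError("emission factors must be non-negative")

    @property
    def electricity_demand_mwh(self) -> float:
        return (
            self.electricity_autoconsumption_biogas_mwh
            + self.electricity_autoconsumption_upgrading_mwh
        )


@dataclass(frozen=True)
class MassBalance:
    """Daily mass flows through the upgrading chain."""

    substrate_in_t_d: float
    biogas_produced_t_d: float
    fugitive_biogas_kg_d: float
    biomethane_out_t_d: float
    offgas_methane_kg_d: float
    offgas_total_t_d: float
    ch4_to_upgrading_kg_d: float

    def closure_residual(self) -> float:
        """biogas - (biomethane + off-gas + fugitive), t/d; ~0 when closed."""
        return self.biogas_produced_t_d - (
            self.biomethane_out_t_d
            + self.offgas_total_t_d
            + self.fugitive_biogas_kg_d / 1000.0
        )


@dataclass(frozen=True)
class EnergyBalance:
    """Annual energy flows (MWh/y unless noted)."""

    gross_biogas_energy_mwh: float
    net_useful_energy_mwh: float
    electricity_out_kwh: float = 0.0   # CHP route
    power_rating_kw: float = 0.0       # CHP route, unrounded
    thermal_demand_mwh: float = 0.0
    electricity_demand_mwh: float = 0.0
    thermal_external_frac: float = 1.0
    electricity_external_frac: float = 1.0


@dataclass(frozen=True)
class GHGBalance:
    """Annual greenhouse-gas account, t CO2e/y; avoided terms are negative."""

    emis_handling_fugitive: float
    emis_electricity: float
    emis_thermal: float
    total_produced: float
    total_avoided: float
    balance: float


def methane_from_substrates(scenario: PlantScenario, substrates=None) -> float:
    """Annual methane production, Nm3/y.

    Passthrough of ``annual_methane_nm3`` when set (default pathway for
    preliminary sizing); otherwise annual VS mass times the blend yield
    ``b0_mix``.  ``substrates`` may supply VS tonnages as a list of
    characterized substrates with annual wet masses.
    """
    if scenario.annual_methane_nm3 is not None:
        return float(scenario.annual_methane_nm3)
    if scenario.b0_mix is None:
        raise ValueError(
            f"{scenario.name}: neither annual_methane_nm3 nor b0_mix configured"
        )
    if substrates is not None:
        vs_t = sum((s.annual_mass or 0.0) * s.vs for s in substrates)
    elif scenario.annual_vs_mass:
        vs_t = sum(scenario.annual_vs_mass.values())
    else:
        raise ValueError(f"{scenario.name}: no VS tonnage available for the B0 chain")
    return vs_t * 1000.0 * scenario.b0_mix  # t -> kg, kg VS * Nm3/kgVS


def chp_balance(scenario: PlantScenario, substrates=None) -> EnergyBalance:
    """Electricity and engine rating for onsite biogas combustion.

    electricity = methane volume x LHV x electrical efficiency; the engine
    rating is annual electricity over annual availability hours.
    """
    if scenario.chp_availability_h <= 0:
        raise ValueError("CHP availability must be positive")
    methane = methane_from_substrates(scenario, substrates)
    gross_kwh = methane * scenario.methane_lhv_vol
    electricity_kwh = gross_kwh * scenario.chp_electrical_efficiency
    power_kw = electricity_kwh / scenario.chp_availability_h
    return EnergyBalance(
        gross_biogas_energy_mwh=gross_kwh / 1000.0,
        net_useful_energy_mwh=electricity_kwh / 1000.0,
        electricity_out_kwh=electricity_kwh,
        power_rating_kw=power_kw,
        thermal_demand_mwh=scenario.thermal_autoconsumption_mwh,
        electricity_demand_mwh=scenario.electricity_demand_mwh,
    )


def biomethane_mass_balance(scenario: PlantScenario) -> MassBalance:
    """Daily flows: substrate in, biogas, fugitive, biomethane, off-gas.

    The CH4 mass fraction of biogas follows from the volumetric methane
    content and the CH4/CO2 densities at normal conditions; the upgrading
    efficiency splits that methane between product gas and off-gas slip.
    Fugitive biogas defaults to the CH4-loss fraction applied to the
    produced biogas unless given directly.
    """
    if scenario.route != "biomethane":
        raise ValueError("mass balance applies to the biomethane route")
    if scenario.biogas_t_per_day is None:
        raise ValueError(
            f"{scenario.name}: biogas_t_per_day required for the mass balance"
        )
    substrate_in = sum(scenario.annual_substrate_mass.values()) / DAYS_PER_YEAR
    biogas = scenario.biogas_t_per_day
    if scenario.fugitive_biogas_kg_per_day is not None:
        fugitive_kg = scenario.fugitive_biogas_kg_per_day
    else:
        fugitive_kg = biogas * 1000.0 * scenario.ch4_loss_frac
    to_upgrading_t = biogas - fugitive_kg / 1000.0
    if to_upgrading_t < 0:
        raise ValueError("fugitive losses exceed produced biogas")
    x = scenario.ch4_vol_frac_biogas
    ch4_mass_frac = (
        x * scenario.methane_density
        / (x * scenario.methane_density + (1.0 - x) * scenario.co2_density)
    )
    ch4_kg = to_upgrading_t * 1000.0 * ch4_mass_frac
    biomethane_t = ch4_kg * scenario.upgrading_efficiency / 1000.0
    offgas_ch4_kg = ch4_kg * (1.0 - scenario.upgrading_efficiency)
    offgas_total_t = to_upgrading_t - biomethane_t
    return MassBalance(
        substrate_in_t_d=substrate_in,
        biogas_produced_t_d=biogas,
        fugitive_biogas_kg_d=fugitive_kg,
        biomethane_out_t_d=biomethane_t,
        offgas_methane_kg_d=offgas_ch4_kg,
        offgas_total_t_d=offgas_total_t,
        ch4_to_upgrading_kg_d=ch4_kg,
    )


def biomethane_energy_balance(
    scenario: PlantScenario, gross_mwh: float | None = None
) -> EnergyBalance:
    """Annual energy: gross biogas energy and net energy in biomethane.

    net = gross x upgrading efficiency (methane slip is the only loss
    modelled); thermal and electric demands are covered externally (no
    internal CHP on this route), so external-coverage fractions are 1.
    """
    if gross_mwh is None:
        gross_mwh = scenario.gross_biogas_energy_mwh
    if gross_mwh is None:
        methane = methane_from_substrates(scenario)
        gross_mwh = methane * scenario.methane_lhv_vol / 1000.0
    if gross_mwh < 0:
        raise ValueError("gross biogas energy must be non-negative")
    return EnergyBalance(
        gross_biogas_energy_mwh=gross_mwh,
        net_useful_energy_mwh=gross_mwh * scenario.upgrading_efficiency,
        thermal_demand_mwh=scenario.thermal_autoconsumption_mwh,
        electricity_demand_mwh=scenario.electricity_demand_mwh,
        thermal_external_frac=1.0,
        electricity_external_frac=1.0,
    )


def ghg_balance(
    scenario: PlantScenario,
    energy: EnergyBalance,
    handling_fugitive_emis: float | None = None,
) -> GHGBalance:
    """Greenhouse-gas account, t CO2e/y.

    Produced terms: substrate handling + fugitive methane (an input, see
    scenario), grid electricity for the autoconsumptions, and natural gas
    burned for the thermal demand.  Avoided term: natural-gas substitution
    by the net biomethane energy (biomethane route) or displaced grid
    electricity plus recovered heat (CHP route), carried with negative sign.
    """
    if handling_fugitive_emis is None:
        handling_fugitive_emis = scenario.handling_fugitive_emissions_tco2e
    if energy.net_useful_energy_mwh < 0 or energy.gross_biogas_energy_mwh < 0:
        raise ValueError("energies must be non-negative")
    if energy.thermal_demand_mwh < 0 or energy.electricity_demand_mwh < 0:
        raise ValueError("demands must be non-negative")
    emis_el = energy.electricity_demand_mwh * scenario.ef_electricity / 1000.0
    emis_th = energy.thermal_demand_mwh * scenario.ef_natural_gas / 1000.0
    if scenario.route == "biomethane":
        avoided = -energy.net_useful_energy_mwh * scenario.ef_natural_gas / 1000.0
    else:
        avoided = -(
            energy.electricity_out_kwh / 1000.0 * scenario.ef_electricity
            + scenario.chp_heat_recovered_mwh * scenario.ef_natural_gas
        ) / 1000.0
    produced = handling_fugitive_emis + emis_el + emis_th
    return GHGBalance(
        emis_handling_fugitive=handling_fugitive_emis,
        emis_electricity=emis_el,
        emis_thermal=emis_th,
        total_produced=produced,
        total_avoided=avoided,
        balance=produced + avoided,
    )


@dataclass(frozen=True)
class PlantReport:
    """Aggregate result of one scenario run."""

    scenario: PlantScenario
    mass: MassBalance | None
    energy: EnergyBalance
    ghg: GHGBalance | None

    def to_dict(self) -> dict:
        out: dict = {"scenario": self.scenario.name, "route": self.scenario.route}
        if self.mass is not None:
            out["mass_balance"] = dataclasses.asdict(self.mass)
        out["energy_balance"] = dataclasses.asdict(self.energy)
        if self.ghg is not None:
            out["ghg_balance"] = dataclasses.asdict(self.ghg)
        return out

    def summary(self) -> str:
        s = self.scenario
        lines = [f"Scenario {s.name} - route: {s.route}", "=" * 40]
        if s.route == "chp":
            e = self.energy
            lines += [
                f"Annual methane (Nm3/y):              {s.annual_methane_nm3:,.0f}",
                f"Electrical energy (kWh/y):           {e.electricity_out_kwh:,.0f}",
                f"Electrical power of engine (kW):     {round_half_away(e.power_rating_kw):.0f}",
            ]
            return "\n".join(lines)
        m, e, g = self.mass, self.energy, self.ghg
        if m is not None:
            lines += [
                f"Substrate input (t/d):               {m.substrate_in_t_d:.2f}",
                f"Biogas produced (t/d):               {m.biogas_produced_t_d:.2f}",
                f"Fugitive biogas (kg/d):              {m.fugitive_biogas_kg_d:.1f}",
                f"Biomethane out (t/d):                {m.biomethane_out_t_d:.3f}",
                f"Off-gas methane (kg/d):              {m.offgas_methane_kg_d:.1f}",
            ]
        lines += [
            f"Gross biogas energy (MWh/y):         {e.gross_biogas_energy_mwh:.1f}",
            f"Net useful energy in biomethane:     {e.net_useful_energy_mwh:.1f}",
            "Thermal autoconsumption covered by external source (%): 100",
            "Electricity autoconsumption covered by external source (%): 100",
        ]
        if g is not None:
            lines += [
                f"GHG handling + fugitive CH4 (t/y):   {g.emis_handling_fugitive:.1f}",
                f"GHG electricity autoconsumption:     {g.emis_electricity:.1f}",
                f"GHG thermal autoconsumption:         {g.emis_thermal:.1f}",
                f"Total GHG produced:                  {g.total_produced:.1f}",
                f"Total GHG avoided:                   {g.total_avoided:.1f}",
                f"GHG balance (t CO2e/y):              {g.balance:.1f}",
            ]
        return "\n".join(lines)


def run_scenario(scenario: PlantScenario, substrates=None) -> PlantReport:
    """Run the full balance chain for one scenario."""
    if scenario.route == "chp":
        energy = chp_balance(scenario, substrates)
        ghg = ghg_balance(scenario, energy)
        return PlantReport(scenario=scenario, mass=None, energy=energy, ghg=ghg)
    mass = (
        biomethane_mass_balance(scenario)
        if scenario.biogas_t_per_day is not None
        else None
    )
    energy = biomethane_energy_balance(scenario)
    ghg = ghg_balance(scenario, energy)
    return PlantReport(scenario=scenario, mass=mass, energy=energy, ghg=ghg)
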