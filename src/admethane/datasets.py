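"""Bundled reference data: coffee-roasting byproduct characterization.

Laboratory reference values for the three byproduct streams of industrial
green-coffee roasting - pellets, roasted coffee powder and green coffee
powder - as produced by two roasting plants of one Italian producer:

* elemental CHNS-O composition, solids content and heating value of each
  stream (dry-matter percentages);
* annual production tonnages per plant and the blend recipes used in the
  fed-batch co-digestion tests (the printed recipe percentages are treated
  as authoritative: they are close to, but not exactly, what the tonnages
  give on either a wet- or VS-mass basis);
* first-order kinetic parameters (B0, k, and biodegradability Y) fitted to
  thermophilic batch tests of the single streams and fed-batch tests of the
  two blends, with duplicate-reactor half-range uncertainty on B0.

These are inputs for worked examples, cross-validation and the reference
plant scenarios; nothing in the modelling code depends on them.
"""

from __future__ import annotations

from .kinetics import KineticParams
from .substrates import MixBasis, MixSpec, Substrate

__all__ = [
    "coffee_substrates",
    "plant_production_t",
    "plant_mix",
    "batch_kinetics",
    "mix_kinetics",
    "PELLETS",
    "ROASTED",
    "GREEN",
]

PELLETS = "pellets"
ROASTED = "roasted_coffee_powder"
GREEN = "green_coffee_powder"

#: Annual (wet) production, t/y, per plant and stream.
_PRODUCTION = {
    "plant_a": {PELLETS: 780.0, GREEN: 70.0, ROASTED: 280.0},
    "plant_b": {PELLETS: 766.0, GREEN: 155.0, ROASTED: 627.0},
}

#: Blend recipes of the fed-batch co-digestion tests (mass fractions).
_MIXES = {
    "plant_a": ((GREEN, 0.062), (ROASTED, 0.263), (PELLETS, 0.675)),
    "plant_b": ((GREEN, 0.092), (ROASTED, 0.429), (PELLETS, 0.479)),
}

#: Batch-test kinetics of the single streams: (B0 [Nm3/kgVS], k [1/d], Y).
_BATCH_KINETICS = {
    PELLETS: KineticParams(b0=0.22, k=0.31, y=0.44),
    ROASTED: KineticParams(b0=0.33, k=0.24, y=0.60),
    GREEN: KineticParams(b0=0.18, k=0.30, y=0.37),
}

#: Fed-batch kinetics of the two blends.
_MIX_KINETICS = {
    "plant_a": KineticParams(b0=0.24, k=0.26, y=0.45),
    "plant_b": KineticParams(b0=0.27, k=0.28, y=0.50),
}

#: Duplicate-reactor half-range on B0, Nm3/kgVS.
B0_HALF_RANGE = {
    PELLETS: 0.01, ROASTED: 0.01, GREEN: 0.01,
    "plant_a": 0.01, "plant_b": 0.02,
}


def coffee_substrates(plant: str | None = None) -> list[Substrate]:
    """The three characterized byproduct streams.

    With ``plant`` given (``"plant_a"`` / ``"plant_b"``) each substrate
    carries that plant's annual tonnage.
    """
    subs = [
        Substrate(
            name=PELLETS, frac_n=0.032, frac_c=0.506, frac_h=0.065,
            frac_s=0.001, frac_o=0.396, ts=0.939, vs=0.861, hhv=13.9,
        ),
        Substrate(
            name=ROASTED, frac_n=0.031, frac_c=0.542, frac_h=0.069,
            frac_s=0.000, frac_o=0.359, ts=0.974, vs=0.928, hhv=12.8,
        ),
        Substrate(
            name=GREEN, frac_n=0.026, frac_c=0.503, frac_h=0.064,
            frac_s=0.000, frac_o=0.408, ts=0.907, vs=0.844, hhv=19.9,
        ),
    ]
    if plant is None:
        return subs
    production = plant_production_t(plant)
    return [s.with_annual_mass(production[s.name]) for s in subs]


def plant_production_t(plant: str) -> dict[str, float]:
    """Annual wet tonnage per stream for one roasting plant."""
    try:
        return dict(_PRODUCTION[plant])
    except KeyError:
        raise KeyError(f"unknown plant {plant!r}; use 'plant_a' or 'plant_b'")


def plant_mix(plant: str) -> MixSpec:
    """Blend recipe of one plant's co-digestion test."""
    if plant not in _MIXES:
        raise KeyError(f"unknown plant {plant!r}; use 'plant_a' or 'plant_b'")
    return MixSpec(components=_MIXES[plant], basis=MixBasis.VS_MASS, name=plant)


def batch_kinetics() -> dict[str, KineticParams]:
    """Single-stream first-order parameters from the batch tests."""
    return dict(_BATCH_KINETICS)


def mix_kinetics(plant: str) -> KineticParams:
    """Blend first-order parameters from the fed-batch tests."""
    try:
        return _MIX_KINETICS[plant]
    except KeyError:
        raise KeyError(f"unknown plant {plant!r}; use 'plant_a' or 'plant_b'")
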