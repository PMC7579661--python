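"""Substrate characterization and stoichiometric methane potential.

A substrate is described by its CHNS-O elemental composition (mass fractions
of dry matter), solids content (TS, VS as fractions of wet mass) and, when
known, the annual wet tonnage produced.  From the composition the chemical
oxygen demand per unit volatile solids follows from the generic oxidation of
``C_a H_b O_c N_d``::

    C_a H_b O_c N_d + (4a + b - 2c - 3d)/4 O2 -> a CO2 + d NH3 + ... ,

so COD/VS = 8 * (4a + b - 2c - 3d) / (12a + b + 16c + 14d) with a, b, c, d
the molar amounts per 100 g of dry matter.  The theoretical (stoichiometric)
methane potential is then COD/VS times the maximum conversion of COD to
methane at normal conditions (0 degC, 1e5 Pa), 0.350 Nm3 CH4 per kg COD.
Sulfur is carried as metadata but does not enter the oxidation balance.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "COD_TO_CH4_NM3_PER_KG",
    "DAYS_PER_YEAR",
    "CompositionError",
    "Substrate",
    "MixBasis",
    "MixSpec",
    "cod_vs_ratio",
    "theoretical_bmp",
    "mix_weighted",
    "daily_mass_flow",
    "mix_from_production",
]

#: Maximum theoretical conversion of COD to methane, Nm3 CH4 per kg COD,
#: at normal conditions (0 degC, 1e5 Pa): 22.414/64 m3 O2-equivalent.
COD_TO_CH4_NM3_PER_KG = 0.350

DAYS_PER_YEAR = 365.0

# Atomic masses used for the per-100-g molar conversion.
_M_C, _M_H, _M_O, _M_N = 12.0, 1.0, 16.0, 14.0


class CompositionError(ValueError):
    """Elemental composition with no computable oxygen demand."""


@dataclass(frozen=True)
class Substrate:
    """One feedstock stream, characterized on a dry-matter basis.

    Parameters
    ----------
    frac_n, frac_c, frac_h, frac_s, frac_o
        Elemental mass fractions of dry matter, in [0, 1].
    ts, vs
        Total and volatile solids as fractions of wet mass; ``vs <= ts``.
    hhv
        Higher heating value, MJ/kg (metadata only).
    annual_mass
        Wet tonnes produced per year (optional).
    """

    name: str
    frac_n: float
    frac_c: float
    frac_h: float
    frac_s: float
    frac_o: float
    ts: float
    vs: float
    hhv: float | None = None
    annual_mass: float | None = None

    def __post_init__(self) -> None:
        for attr in ("frac_n", "frac_c", "frac_h", "frac_s", "frac_o", "ts", "vs"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.name}: {attr}={v} outside [0, 1]")
        if self.vs > self.ts + 1e-12:
            raise ValueError(f"{self.name}: VS ({self.vs}) exceeds TS ({self.ts})")
        elemental = self.frac_n + self.frac_c + self.frac_h + self.frac_s + self.frac_o
        # 2% headroom for analytical rounding of CHNS-O rows.
        if elemental > 1.02:
            raise ValueError(
                f"{self.name}: elemental fractions sum to {elemental:.4f} > 1.02"
            )

    def molar_amounts(self) -> tuple[float, float, float, float]:
        """(a, b, c, d) = mol C, H, O, N per 100 g dry matter."""
        return (
            100.0 * self.frac_c / _M_C,
            100.0 * self.frac_h / _M_H,
            100.0 * self.frac_o / _M_O,
            100.0 * self.frac_n / _M_N,
        )

    def with_annual_mass(self, annual_mass: float) -> "Substrate":
        return replace(self, annual_mass=annual_mass)


class MixBasis(str, enum.Enum):
    """Basis on which mix fractions are expressed."""

    VS_MASS = "vs_mass"
    WET_MASS = "wet_mass"


@dataclass(frozen=True)
class MixSpec:
    """A named blend of substrates given as (name, fraction) pairs.

    Fractions must be non-negative and sum to 1 within 0.005 (printed
    percentages are often rounded to one decimal).
    """

    components: tuple[tuple[str, float], ...]
    basis: MixBasis = MixBasis.VS_MASS
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(
            (str(n), float(f)) for n, f in self.components
        ))
        object.__setattr__(self, "basis", MixBasis(self.basis))
        if any(f < 0 for _, f in self.components):
            raise ValueError("mix fractions must be non-negative")
        total = sum(f for _, f in self.components)
        if abs(total - 1.0) > 0.005:
            raise ValueError(f"mix fractions sum to {total:.4f}, expected 1.0 +/- 0.005")

    @property
    def fractions(self) -> dict[str, float]:
        return dict(self.components)


def cod_vs_ratio(s: Substrate) -> float:
    """Chemical oxygen demand per unit volatile solids, g COD / g VS.

    Homogeneous of degree zero in the mass fractions: any uniform rescaling
    (percent vs fraction input, moisture bookkeeping) leaves it unchanged.

    Raises
    ------
    CompositionError
        If the composition has no oxidizable content (4a + b - 2c - 3d <= 0)
        or a zero denominator (no C/H/O/N at all).
    """
    if s.frac_c <= 0:
        raise CompositionError(f"{s.name}: no carbon content, COD undefined")
    a, b, c, d = s.molar_amounts()
    numerator = 4.0 * a + b - 2.0 * c - 3.0 * d
    denominator = 12.0 * a + b + 16.0 * c + 14.0 * d
    if denominator == 0.0:
        raise CompositionError(f"{s.name}: empty composition, COD/VS undefined")
    if numerator <= 0.0:
        raise CompositionError(
            f"{s.name}: 4a+b-2c-3d = {numerator:.4g} <= 0, no oxidizable content"
        )
    return 8.0 * numerator / denominator


def theoretical_bmp(s: Substrate) -> float:
    """Theoretical methane potential Bth, Nm3 CH4 per kg VS.

    Stoichiometric upper bound on the biochemical methane potential:
    COD/VS times 0.350 Nm3 CH4 / kg COD at normal conditions.
    """
    return cod_vs_ratio(s) * COD_TO_CH4_NM3_PER_KG


def mix_weighted(params_by_substrate: Mapping[str, float], mix: MixSpec) -> float:
    """Fraction-weighted average of a per-substrate quantity over a mix.

    Linear in the values; used to carry single-substrate kinetic parameters
    (B0, k, Y) over to a blend.
    """
    missing = [n for n, _ in mix.components if n not in params_by_substrate]
    if missing:
        raise KeyError(f"mix components without a value: {missing}")
    return sum(f * params_by_substrate[n] for n, f in mix.components)


def daily_mass_flow(substrates: Iterable[Substrate]) -> float:
    """Total substrate input flow, wet t/d, from annual tonnages (365 d/y)."""
    total = 0.0
    for s in substrates:
        if s.annual_mass is None:
            raise ValueError(f"{s.name}: annual_mass not set")
        total += s.annual_mass
    return total / DAYS_PER_YEAR


def mix_from_production(
    substrates: Sequence[Substrate], basis: MixBasis | str = MixBasis.VS_MASS,
    name: str = "",
) -> MixSpec:
    """Derive mix fractions from annual production tonnages.

    On a wet-mass basis each substrate's weight is its annual tonnage; on a
    VS-mass basis the tonnage is first multiplied by the VS fraction of wet
    mass.  Useful to build new blends; note that reported blend recipes are
    often rounded and need not be exactly reproducible from tonnages.
    """
    basis = MixBasis(basis)
    weights = []
    for s in substrates:
        if s.annual_mass is None:
            raise ValueError(f"{s.name}: annual_mass not set")
        w = s.annual_mass if basis is MixBasis.WET_MASS else s.annual_mass * s.vs
        weights.append((s.name, w))
    total = sum(w for _, w in weights)
    if total <= 0:
        raise ValueError("total production is zero; no mix derivable")
    return MixSpec(
        components=tuple((n, w / total) for n, w in weights), basis=basis, name=name
    )
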