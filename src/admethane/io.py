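"""Delimited-text and YAML interfaces.

File formats
------------
substrate table : CSV, header ``name,N,C,H,S,O,TS,VS,HHV,annual_mass``.
    Composition columns are either fractions (0-1) or percent (0-100); the
    caller states which with ``units`` - there is no silent autodetection.
methane series : CSV, header ``day,volume_nm3``, one file per digester.
feed schedule : CSV, header ``day,mass_vs_kg``.
scenario : YAML mapping mirroring the plant-parameter table keys; two
    reference scenarios (``plant_a``, ``plant_b``) ship with the package,
    plus variants carrying the alternate parameter set.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinetics import FeedSchedule, MethaneSeries
from .plant import PlantScenario
from .substrates import MixSpec, Substrate

__all__ = [
    "read_substrate_table",
    "write_substrate_table",
    "read_methane_series",
    "write_methane_series",
    "read_schedule",
    "write_schedule",
    "load_scenario",
    "packaged_scenario",
    "packaged_substrate_table",
    "write_manifest",
    "read_manifest",
]

_SUBSTRATE_COLUMNS = ["name", "N", "C", "H", "S", "O", "TS", "VS", "HHV", "annual_mass"]
_FRACTION_COLS = ["N", "C", "H", "S", "O", "TS", "VS"]


class TableFormatError(ValueError):
    """Malformed delimited input; carries the offending row where known."""


def _scale(units: str) -> float:
    if units == "fraction":
        return 1.0
    if units == "percent":
        return 0.01
    raise ValueError(f"units must be 'fraction' or 'percent', got {units!r}")


def read_substrate_table(path: str | Path, units: str = "percent") -> list[Substrate]:
    """Read a substrate characterization table (CSV)."""
    scale = _scale(units)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises several parser error types
        raise TableFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in _SUBSTRATE_COLUMNS[:8] if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing}")
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(
                Substrate(
                    name=str(row["name"]),
                    frac_n=float(row["N"]) * scale,
                    frac_c=float(row["C"]) * scale,
                    frac_h=float(row["H"]) * scale,
                    frac_s=float(row["S"]) * scale,
                    frac_o=float(row["O"]) * scale,
                    ts=float(row["TS"]) * scale,
                    vs=float(row["VS"]) * scale,
                    hhv=None if pd.isna(row.get("HHV")) else float(row["HHV"]),
                    annual_mass=(
                        None
                        if "annual_mass" not in df.columns
                        or pd.isna(row.get("annual_mass"))
                        else float(row["annual_mass"])
                    ),
                )
            )
        except (TypeError, ValueError) as exc:
            raise TableFormatError(f"{path}: row {idx + 2}: {exc}") from exc
    return out


def write_substrate_table(
    substrates: list[Substrate], path: str | Path, units: str = "percent"
) -> None:
    scale = 1.0 / _scale(units)
    rows = [
        {
            "name": s.name,
            "N": s.frac_n * scale,
            "C": s.frac_c * scale,
            "H": s.frac_h * scale,
            "S": s.frac_s * scale,
            "O": s.frac_o * scale,
            "TS": s.ts * scale,
            "VS": s.vs * scale,
            "HHV": s.hhv,
            "annual_mass": s.annual_mass,
        }
        for s in substrates
    ]
    pd.DataFrame(rows, columns=_SUBSTRATE_COLUMNS).to_csv(path, index=False)


def read_methane_series(
    path: str | Path,
    volume_m3: float | None = None,
    vs_conc_kg_m3: float | None = None,
    name: str | None = None,
) -> MethaneSeries:
    """Read one digester's cumulative methane series (``day,volume_nm3``)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise TableFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    for col in ("day", "volume_nm3"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing column {col!r}")
    return MethaneSeries(
        times=df["day"].to_numpy(dtype=float),
        cumulative_volume=df["volume_nm3"].to_numpy(dtype=float),
        volume_m3=volume_m3,
        vs_conc_kg_m3=vs_conc_kg_m3,
        name=name if name is not None else Path(path).stem,
    )


def write_methane_series(series: MethaneSeries, path: str | Path) -> None:
    pd.DataFrame(
        {"day": series.times, "volume_nm3": series.cumulative_volume}
    ).to_csv(path, index=False)


def read_schedule(path: str | Path) -> FeedSchedule:
    """Read a feeding schedule (``day,mass_vs_kg``)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise TableFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    for col in ("day", "mass_vs_kg"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing column {col!r}")
    return FeedSchedule(
        events=tuple(zip(df["day"].astype(float), df["mass_vs_kg"].astype(float)))
    )


def write_schedule(schedule: FeedSchedule, path: str | Path) -> None:
    pd.DataFrame(
        {"day": schedule.times, "mass_vs_kg": schedule.masses}
    ).to_csv(path, index=False)


def _mix_from_config(cfg: dict) -> MixSpec:
    comps = cfg["components"]
    if isinstance(comps, dict):
        comps = tuple(comps.items())
    else:
        comps = tuple((c["name"], c["fraction"]) for c in comps)
    return MixSpec(
        components=comps,
        basis=cfg.get("basis", "vs_mass"),
        name=cfg.get("name", ""),
    )


def load_scenario(source: str | Path | dict) -> PlantScenario:
    """Build a :class:`PlantScenario` from a YAML file or a mapping."""
    if isinstance(source, dict):
        cfg = dict(source)
    else:
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, dict):
            raise TableFormatError(f"{source}: scenario file is not a mapping")
    if "mix" in cfg and cfg["mix"] is not None:
        cfg["mix"] = _mix_from_config(cfg["mix"])
    cfg.pop("note", None)
    try:
        return PlantScenario(**cfg)
    except TypeError as exc:
        raise TableFormatError(f"scenario config: {exc}") from exc


def packaged_scenario(name: str) -> PlantScenario:
    """Load a scenario shipped with the package (``plant_a``, ``plant_b``,
    ``plant_a_table3``, ``plant_b_table3``)."""
    ref = resources.files("admethane.data") / f"{name}.yaml"
    with resources.as_file(ref) as path:
        return load_scenario(path)


def packaged_substrate_table() -> list[Substrate]:
    """The bundled coffee-roasting byproduct characterization table."""
    ref = resources.files("admethane.data") / "coffee_substrates.csv"
    with resources.as_file(ref) as path:
        return read_substrate_table(path, units="percent")


def write_manifest(manifest: dict, path: str | Path) -> None:
    """JSON manifest (config + ground truth) with stable key order."""
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
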