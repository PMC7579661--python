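"""Diagnostic plots: fitted methane curves and balance bar charts."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .kinetics import FirstOrderResults, MethaneSeries
from .plant import PlantReport

__all__ = ["plot_fit", "plot_ghg_balance"]


def plot_fit(
    result: FirstOrderResults, path: str | Path, title: str = ""
) -> None:
    """Observed points with the fitted first-order curve."""
    series = result.model.series
    t_dense = np.linspace(0.0, float(series.times.max()), 200)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(series.times, series.cumulative_volume, "o", label="observed")
    ax.plot(t_dense, result.predict(t_dense), "-", label="first-order fit")
    ax.set_xlabel("time (d)")
    ax.set_ylabel("cumulative CH$_4$ (Nm$^3$)")
    ax.set_title(
        title
        or f"B0={result.params.b0:.3f} Nm3/kgVS, k={result.params.k:.3f} 1/d"
    )
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ghg_balance(report: PlantReport, path: str | Path) -> None:
    """Produced vs avoided annual GHG terms for one scenario."""
    g = report.ghg
    if g is None:
        raise ValueError("report carries no GHG balance")
    labels = ["handling+fugitive", "electricity", "thermal", "avoided", "balance"]
    values = [
        g.emis_handling_fugitive, g.emis_electricity, g.emis_thermal,
        g.total_avoided, g.balance,
    ]
    colors = ["#b65c46" if v >= 0 else "#4a7d50" for v in values]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(labels, values, color=colors)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_ylabel("t CO$_2$e / y")
    ax.set_title(f"GHG balance: {report.scenario.name}")
    plt.setp(ax.get_xticklabels(), rotation=30, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
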