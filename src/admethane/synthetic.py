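"""Synthetic batch and fed-batch digestion datasets with known truth.

Emulates the laboratory protocol the kinetics module is meant to analyse:
thermophilic lab digesters read every working day (Monday-Friday), duplicate
test reactors plus duplicate inoculum-only blanks, cumulative methane logged
at normal conditions.  Ground truth (B0, k, background) is always emitted
alongside the data so parameter-recovery tests can bound estimation error as
a function of the noise level.

Noise enters as an independent Gaussian reading error on each gas-volume
measurement: a reading error perturbs the increment it closes and the next
one with opposite sign, so the noise is applied to increments and
re-accumulated, cumulative curves are unbiased and non-decreasing in
expectation, and an occasional locally decreasing pair of readings - which
real noisy curves show and the fitting routine tolerates with a warning -
can occur.  Increments are deliberately not floored at zero: a one-sided
floor inflates the plateau and biases B0 upward by several percent.
Blanks share the same first-order background term added to the test
reactors, so subtracting the blank mean recovers the substrate signal in
expectation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kinetics import (
    FeedSchedule,
    KineticParams,
    MethaneSeries,
    batch_curve,
    fedbatch_simulate,
)

__all__ = [
    "SynthConfig",
    "observation_days",
    "make_batch_dataset",
    "make_fedbatch_dataset",
    "blank_correct",
    "AlignmentError",
]

#: Default methane fraction of biogas, v/v, when biogas rather than methane
#: volumes are requested (typical of well-run thermophilic digesters).
DEFAULT_CH4_VOL_FRAC = 0.50


class AlignmentError(ValueError):
    """Series on different observation grids cannot be combined."""


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of one synthetic digestion experiment.

    Defaults mirror the lab protocol being emulated: 18-day batch tests in
    2 L working volume (fed-batch: 35 days, 4 L), weekday-only readings
    starting on a Monday, duplicate test reactors and duplicate blanks,
    measurement noise of 2% of the asymptotic yield per reading, and an
    inoculum background worth 10% of the test asymptote.
    """

    true_params: KineticParams
    vs_conc: float = 20.0          # kg VS/m3 charged (batch)
    volume: float = 0.002          # m3 working volume
    duration: int = 18             # days
    noise_sd_frac: float = 0.02    # sd of increment noise / asymptotic yield
    observation_pattern: str = "weekdays"   # or "daily"
    blank_yield_frac: float = 0.10  # inoculum background / test asymptote
    blank_k: float | None = None    # background rate constant; default = true k
    n_replicates: int = 2
    n_blanks: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.noise_sd_frac < 0:
            raise ValueError("noise_sd_frac must be non-negative")
        if self.blank_yield_frac < 0:
            raise ValueError("blank_yield_frac must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("need at least one test replicate")
        if self.n_blanks < 0:
            raise ValueError("n_blanks must be non-negative")
        if self.observation_pattern not in ("daily", "weekdays"):
            raise ValueError(
                f"unknown observation pattern {self.observation_pattern!r}"
            )

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["true_params"] = dataclasses.asdict(self.true_params)
        return d


def observation_days(duration: int, pattern: str = "weekdays") -> np.ndarray:
    """Observation days 1..duration; weekday pattern assumes day 1 = Monday.

    With weekday readings the gas bag is still cumulated over the weekend,
    so Monday's reading covers three days - only the observation grid
    changes, not the underlying curve.
    """
    days = np.arange(1, duration + 1, dtype=float)
    if pattern == "daily":
        return days
    if pattern == "weekdays":
        return days[((days - 1) % 7) < 5]
    raise ValueError(f"unknown observation pattern {pattern!r}")


def _noisy_accumulate(
    clean_cumulative: np.ndarray, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Apply per-reading Gaussian errors through the increments.

    Each cumulative reading carries an independent N(0, sd) error; the
    error enters the increment it closes and leaves through the next one,
    so increments receive the first difference of the reading errors and
    re-accumulation reproduces reading-level noise.  The result is clipped
    at zero (volumes are non-negative) but not forced monotone.
    """
    increments = np.diff(clean_cumulative, prepend=0.0)
    if sd > 0:
        reading_err = rng.normal(0.0, sd, size=increments.shape)
        increments = increments + np.diff(reading_err, prepend=0.0)
    return np.maximum(np.cumsum(increments), 0.0)


def _background_curve(
    cfg: SynthConfig, asymptote: float, times: np.ndarray
) -> np.ndarray:
    """First-order inoculum background shared by tests and blanks, Nm3."""
    if cfg.blank_yield_frac == 0:
        return np.zeros_like(times)
    k_b = cfg.blank_k if cfg.blank_k is not None else cfg.true_params.k
    return cfg.blank_yield_frac * asymptote * (-np.expm1(-k_b * times))


def _assemble(
    cfg: SynthConfig,
    times: np.ndarray,
    substrate_cum: np.ndarray,
    asymptote: float,
    vs_conc_meta: float | None,
) -> tuple[list[MethaneSeries], list[MethaneSeries]]:
    rng = np.random.default_rng(cfg.seed)
    background = _background_curve(cfg, asymptote, times)
    sd = cfg.noise_sd_frac * asymptote
    tests = [
        MethaneSeries(
            times=times,
            cumulative_volume=_noisy_accumulate(substrate_cum + background, sd, rng),
            volume_m3=cfg.volume,
            vs_conc_kg_m3=vs_conc_meta,
            name=f"test_{i + 1}",
        )
        for i in range(cfg.n_replicates)
    ]
    blanks = [
        MethaneSeries(
            times=times,
            cumulative_volume=_noisy_accumulate(background, sd, rng),
            volume_m3=cfg.volume,
            name=f"blank_{i + 1}",
        )
        for i in range(cfg.n_blanks)
    ]
    return tests, blanks


def make_batch_dataset(
    cfg: SynthConfig,
) -> tuple[list[MethaneSeries], list[MethaneSeries], dict]:
    """Synthetic batch test: replicates, blanks and the truth record."""
    times = observation_days(cfg.duration, cfg.observation_pattern)
    clean = batch_curve(cfg.true_params, cfg.vs_conc, cfg.volume, times)
    asymptote = cfg.vs_conc * cfg.volume * cfg.true_params.b0
    tests, blanks = _assemble(
        cfg, times, clean.cumulative_volume, asymptote, cfg.vs_conc
    )
    truth = {
        "mode": "batch",
        "config": cfg.to_manifest(),
        "asymptote_nm3": asymptote,
        "total_vs_kg": cfg.vs_conc * cfg.volume,
        "n_observations": int(times.size),
    }
    return tests, blanks, truth


def make_fedbatch_dataset(
    cfg: SynthConfig,
    schedule: FeedSchedule,
    y_at_entry: bool = False,
) -> tuple[list[MethaneSeries], list[MethaneSeries], dict]:
    """Synthetic fed-batch test over an impulse feeding schedule."""
    times = observation_days(cfg.duration, cfg.observation_pattern)
    _, clean = fedbatch_simulate(
        cfg.true_params, schedule, cfg.volume, times, y_at_entry=y_at_entry
    )
    fed = schedule.total_vs_kg
    scale = cfg.true_params.y if (y_at_entry and cfg.true_params.y) else 1.0
    asymptote = scale * fed * cfg.true_params.b0
    tests, blanks = _assemble(cfg, times, clean.cumulative_volume, asymptote, None)
    truth = {
        "mode": "fedbatch",
        "config": cfg.to_manifest(),
        "schedule": [list(e) for e in schedule.events],
        "y_at_entry": y_at_entry,
        "asymptote_nm3": asymptote,
        "total_vs_kg": fed,
        "n_observations": int(times.size),
    }
    return tests, blanks, truth


def blank_correct(
    test: MethaneSeries, blanks: list[MethaneSeries]
) -> MethaneSeries:
    """Subtract the mean inoculum-only curve from a test reactor.

    The corrected series is floored at zero and made non-decreasing with a
    running maximum (noise can push individual corrected readings slightly
    negative or non-monotone).
    """
    if not blanks:
        return test
    for b in blanks:
        if b.times.shape != test.times.shape or not np.allclose(b.times, test.times):
            raise AlignmentError(
                f"blank {b.name!r} observation days differ from test {test.name!r}"
            )
    mean_blank = np.mean([b.cumulative_volume for b in blanks], axis=0)
    corrected = np.maximum(test.cumulative_volume - mean_blank, 0.0)
    corrected = np.maximum.accumulate(corrected)
    return MethaneSeries(
        times=test.times,
        cumulative_volume=corrected,
        volume_m3=test.volume_m3,
        vs_conc_kg_m3=test.vs_conc_kg_m3,
        name=f"{test.name}_corrected" if test.name else "corrected",
    )
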