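import numpy as np
import pytest

from admethane import FeedSchedule, KineticParams
from admethane.datasets import batch_kinetics, coffee_substrates, plant_mix


@pytest.fixture(scope="session")
def substrates():
    """The three characterized coffee-roasting byproduct streams."""
    return {s.name: s for s in coffee_substrates()}


@pytest.fixture(scope="session")
def plant_substrates():
    return {
        plant: coffee_substrates(plant) for plant in ("plant_a", "plant_b")
    }


@pytest.fixture(scope="session")
def mixes():
    return {plant: plant_mix(plant) for plant in ("plant_a", "plant_b")}


@pytest.fixture(scope="session")
def single_params():
    """Batch-test first-order parameters of the single streams."""
    return batch_kinetics()


@pytest.fixture
def weekly_schedule():
    """Five weekly feedings of 10 g VS over a 35-day fed-batch test."""
    return FeedSchedule(events=tuple((float(d), 0.01) for d in (0, 7, 14, 21, 28)))


def analytic_fedbatch(params: KineticParams, feed_times, feed_masses, volume, times):
    """Closed-form piecewise solution of the impulse-fed first-order model.

    Independent oracle: superposition of one exponential pool per feeding,

        u(t) = sum_i m_i/V * exp(-k (t - t_i)) for t >= t_i,
        B(t) = B0 * sum_i m_i * (1 - exp(-k (t - t_i))) for t >= t_i.
    """
    times = np.asarray(times, dtype=float)
    pool = np.zeros_like(times)
    methane = np.zeros_like(times)
    for t_i, m_i in zip(feed_times, feed_masses):
        active = times >= t_i
        dt = times[active] - t_i
        pool[active] += m_i / volume * np.exp(-params.k * dt)
        methane[active] += params.b0 * m_i * -np.expm1(-params.k * dt)
    return pool, methane
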