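import numpy as np
import pytest

from grazetrack import SimConfig, TrackSequence, simulate_track


@pytest.fixture
def straight_track():
    """40 positions on a straight line, constant 5 m steps, 20 s interval."""
    n = 40
    return TrackSequence(
        "straight", 20.0, 20.0 * np.arange(n), 5.0 * np.arange(n), np.zeros(n),
        np.full(n, "walking", dtype=object),
    )


@pytest.fixture
def sim_track():
    """Small noisy cow-like simulated bout (500 positions)."""
    return simulate_track(SimConfig(n_positions=500, seed=42)).track


@pytest.fixture
def random_track():
    """Irregular but gap-free random walk, for metric property checks."""
    rng = np.random.default_rng(7)
    n = 60
    steps = rng.exponential(3.0, size=(n - 1, 2)) * rng.choice([-1, 1], size=(n - 1, 2))
    xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return TrackSequence("rw", 20.0, 20.0 * np.arange(n), xy[:, 0], xy[:, 1])
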