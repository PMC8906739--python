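import math

import numpy as np
import pytest

from reachpop.synthetic import SessionConfig, generate_session, generate_trajectories


def small_config(**overrides) -> SessionConfig:
    """A reduced session: 45 trials, 16 units — fast enough for CI-style runs."""
    defaults = dict(
        n_trials=45,
        trials_per_block=15,
        n_units=16,
        seed=11,
    )
    defaults.update(overrides)
    return SessionConfig(**defaults)


@pytest.fixture(scope="session")
def session_small():
    return generate_session(small_config())


@pytest.fixture(scope="session")
def trajectories_small():
    cfg = small_config()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    return generate_trajectories(cfg, rng)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
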