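import dataclasses

import numpy as np
import pytest

from swarmevo.config import ArenaConfig, BehaviorConfig, PheromoneConfig, SimConfig


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """Small fast arena for unit-level simulation tests (8 robots, 600 ticks)."""
    return SimConfig(
        arena=dataclasses.replace(
            ArenaConfig(), field_length_mm=2100.0, n_steps=600, n_robots=8,
            food_light_radius_mm=300.0),
    ).validate()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
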