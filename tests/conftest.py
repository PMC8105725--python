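import numpy as np
import pytest

from myddo.simulate import SimulationConfig


@pytest.fixture
def noise_free_config() -> SimulationConfig:
    """Simulation with every stochastic intensity term disabled."""
    return SimulationConfig(
        image_shape=(96, 96), n_frames=20, gfp_unit_cv=0.0, shot_noise=False,
        read_noise_sd=0.0, camera_offset=0.0, nucleation_rate=0.0, seed=0,
    )


@pytest.fixture
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
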