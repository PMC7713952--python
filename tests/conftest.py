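import numpy as np
import pytest

import ecobreak as eb


@pytest.fixture(scope="session")
def default_params() -> eb.BreakpointParams:
    """True parameters of the default simulation model."""
    return eb.SimulationConfig().params


@pytest.fixture(scope="session")
def noiseless_data(default_params) -> eb.XYData:
    """Noise-free draw from the default piecewise model on 50 points."""
    cfg = eb.SimulationConfig()
    x = np.linspace(cfg.x_min, cfg.x_max, 50)
    return eb.XYData(x, eb.piecewise_mean(x, default_params))


@pytest.fixture(scope="session")
def noisy_small() -> eb.XYData:
    """One noisy n=30, df=10 dataset from the simulator."""
    return eb.generate_dataset(eb.SimulationConfig(n=30, df=10), seed=7)


@pytest.fixture(scope="session")
def noisy_large() -> eb.XYData:
    """One noisy n=150, df=20 dataset from the simulator."""
    return eb.generate_dataset(eb.SimulationConfig(n=150, df=20), seed=7)
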