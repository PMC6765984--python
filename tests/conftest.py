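import numpy as np
import pytest

import airfusion as af


@pytest.fixture(scope="session")
def small_grid():
    return af.GridDefinition.regular(10, 10, lat0=35.0, lon0=-100.0, dlat=0.1, dlon=0.1)


@pytest.fixture(scope="session")
def scenario_small():
    """A 10x12 grid, 60-day scenario with all three sampling frequencies."""
    scn = af.SyntheticScenario(n_rows=10, n_cols=12, n_days=60, n_sites=12, seed=42)
    return af.generate_scenario(scn)


@pytest.fixture(scope="session")
def scenario_noiseless():
    """Noiseless, bias-free scenario with beta = 1: obs = alpha*model exactly,
    and the annual-mean fit recovers the parameters without Jensen slack."""
    scn = af.SyntheticScenario(n_rows=10, n_cols=12, n_days=40, n_sites=10, seed=5,
                               noise_sigma=0.0, bias_amplitude=0.0,
                               bias_temporal_amplitude=0.0, beta=1.0)
    return af.generate_scenario(scn)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
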