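import numpy as np
import pytest

from trackephys import SimulationConfig, simulate_session
from trackephys.pipeline import analyze_session


@pytest.fixture(scope="session")
def base_cfg():
    """A compact but fully featured session: 5 minutes, 15 CA1 + 8 VC units,
    frequent ripples so event-dependent analyses have material to work on."""
    return SimulationConfig(
        session_duration=300.0,
        n_ca1_units=15,
        n_vc_units=8,
        ripple_rate=20.0,
        hvs_rate=1.0,
        eht_rate=1.0,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def pre_session(base_cfg):
    return simulate_session(base_cfg, "PRE")


@pytest.fixture(scope="session")
def pre_analysis(pre_session):
    bundle, _ = pre_session
    return analyze_session(bundle)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
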