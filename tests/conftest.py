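import numpy as np
import pytest

import thalwave as tw


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def delay_params():
    """Calibrated rebound-element parameters (cached across tests)."""
    return tw.calibrate_delay_element()


@pytest.fixture(scope="session")
def small_closed_loop():
    """One 30x30 closed-loop trajectory shared by several tests."""
    cfg = tw.make_config("closed_loop_default", rows=30, cols=30,
                         duration=200.0, seed=1)
    return tw.run(cfg)
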