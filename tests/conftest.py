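import numpy as np
import pytest

from earbci import Recording, SSVEPSimConfig, simulate_ssvep_trials


@pytest.fixture
def small_recording():
    rng = np.random.default_rng(42)
    data = rng.standard_normal((3, 1000)) * 20.0
    return Recording(data, 250.0, ["L1", "L2", "OZ"])


@pytest.fixture(scope="session")
def noiseless_nine_class():
    """Noiseless 9-target SSVEP set (2 blocks), shared across tests."""
    cfg = SSVEPSimConfig(noise_rms_uV=0.0, n_blocks=3, trial_s=4.0, seed=0)
    return simulate_ssvep_trials(cfg)


@pytest.fixture(scope="session")
def moderate_nine_class():
    """The default moderate-noise 9-target condition (6 blocks), seed 1."""
    return simulate_ssvep_trials(SSVEPSimConfig(seed=1))
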