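import numpy as np
import pytest

import hrvperiod as hp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_ensemble():
    """Reduced oscillator ensemble (5 noise levels x 5 realizations) for
    property tests that only need the qualitative C-ladder."""
    return hp.generate_ensemble(c_values=(0.0, 10.0, 20.0, 30.0, 40.0),
                                n_realizations=5, master_seed=7)


@pytest.fixture(scope="session")
def cmv_rr():
    return hp.generate_rr_cmv(n_beats=1000, mean_rr_ms=170.0, mod_freq_hz=1.0,
                              mod_depth_ms=10.0, jitter_ms=1.0,
                              rng=np.random.default_rng(3))


@pytest.fixture(scope="session")
def bvv_rr():
    return hp.generate_rr_bvv(n_beats=1000, mean_rr_ms=170.0,
                              band_hz=(0.5, 1.5), mod_depth_ms=10.0,
                              jitter_ms=1.0, rng=np.random.default_rng(3))
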