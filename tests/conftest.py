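import numpy as np
import pytest

from ncreann import NMVARSpec, simulate_nmvar


@pytest.fixture(scope="session")
def dense_var_data():
    """Linear VAR(2), M=3, all edges carrying distinct strengths."""
    from ncreann.studies import dense_var_spec
    spec = dense_var_spec(seed=7, n_samples=20000)
    data, edges = simulate_nmvar(spec)
    return spec, data, edges


@pytest.fixture(scope="session")
def ar1_data():
    spec = NMVARSpec(M=1, p=1, A=np.array([[[0.5]]]), noise_sd=1.0,
                     n_samples=10000, n_trials=1, seed=11)
    data, _ = simulate_nmvar(spec)
    return data


@pytest.fixture()
def grid_positions():
    def make(n_channels, side=None):
        side = side or int(np.ceil(np.sqrt(n_channels)))
        return np.array([[i % side, i // side]
                         for i in range(n_channels)], dtype=float)
    return make
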