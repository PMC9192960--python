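import numpy as np
import pytest

from decpipe.containers import NeuralTimeSeries
from decpipe.synth_cohort import VarSpec, constant_coeffs, generate_tv_var


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_region_static_series():
    """Stable 2-region lag-1 VAR with a known standardized 1->2 coefficient of 0.6.

    Innovation SDs are chosen so both channels have unit stationary
    variance, making the raw coefficient equal to its standardized value.
    """
    A = np.array([[0.0, 0.0], [0.6, 0.0]])
    spec = VarSpec(2, 1, constant_coeffs(A), innovation_sd=np.array([1.0, 0.8]),
                   length=5000, dt=2.0)
    return generate_tv_var(spec, seed=7)


@pytest.fixture
def white_noise_series(rng):
    return NeuralTimeSeries(rng.normal(0, 1, (2000, 2)), dt=2.0)
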