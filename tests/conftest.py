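import numpy as np
import pytest

from thalburst import TCModel, condition_params, reference_neuron
from thalburst.gabab import CONDITIONS


@pytest.fixture(scope="session")
def ref_params():
    return reference_neuron()


@pytest.fixture(scope="session")
def ref_model(ref_params):
    return TCModel(ref_params)


@pytest.fixture(scope="session")
def ipsc_traces_200(ref_model):
    """IPSC-protocol sweeps of the reference neuron, all four conditions at
    200 % amplitude and -70 mV hold (shared across detection/discrepancy
    tests to keep the suite fast)."""
    out = {}
    for cond in CONDITIONS:
        k = condition_params(cond).with_scale(2.0)
        out[cond] = ref_model.run_ipsc_protocol(k, v_hold=-70.0, rec_dt=1.0)
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
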