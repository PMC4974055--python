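import numpy as np
import pytest

import respnet
from respnet import synth


@pytest.fixture(scope="session")
def small_recording():
    """A modest coupled recording used by several pipeline-level tests."""
    g = respnet.generate_network(
        respnet.NetworkSpec(n_cells=30, topology="small_world", k=4,
                            rewire_p=0.1, seed=3))
    dyn = respnet.DynamicsSpec(duration=300.0)
    return respnet.simulate_recording(g, dyn, seed=4)


@pytest.fixture()
def noise_traces():
    """Independent Gaussian traces with no network structure, for null tests."""
    rng = np.random.default_rng(12)
    vals = rng.normal(0, 1, size=(20, 300))
    return respnet.NormalizedTraceSet(values=vals, frame_interval=0.5,
                                      roi_ids=[f"n{i}" for i in range(20)])


@pytest.fixture()
def noiseless_dynamics():
    return synth.DynamicsSpec(noise_sd=0.0, drift_amplitude=0.0,
                              rate_jitter_cv=0.0, duration=300.0)
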