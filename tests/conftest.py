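import numpy as np
import pytest

from striatal_lsm.circuit import ScaleFactors, SynapseRanges, build_circuit


@pytest.fixture(scope="session")
def small_circuit():
    """A scaled-down circuit (50 MSN, 5 FSI, 20 CTX) for engine-level tests."""
    return build_circuit(
        n_msn=50, n_fsi=5, n_cortex=20,
        scale=ScaleFactors(w_s=18.0, w_c=113.0),
        seed=42,
    )


@pytest.fixture(scope="session")
def reference_circuit():
    """A full-size circuit at the reference scale factors {w_s=18, w_c=113}."""
    return build_circuit(scale=ScaleFactors(w_s=18.0, w_c=113.0), seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
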