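import logging

import numpy as np
import pytest

from icaperf.phantom import PhantomSpec, build_phantom

logging.getLogger("icaperf").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """One noise-free phantom realization shared across tests."""
    spec = PhantomSpec(cnr=np.inf, seed=0)
    series, truth = build_phantom(spec)
    return spec, series, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    """A CNR-50 phantom realization shared across tests."""
    spec = PhantomSpec(cnr=50.0, seed=7)
    series, truth = build_phantom(spec)
    return spec, series, truth
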