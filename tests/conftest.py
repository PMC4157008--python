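import numpy as np
import pytest

from peakswarm import SynthConfig, generate, make_separable_fixture


@pytest.fixture(scope="session")
def toy_samples():
    # admits two candidates: (pp=2, vp1=1, vp2=3) and (pp=4, vp1=3, vp2=5)
    return np.array([5.0, 1.0, 4.0, 2.0, 6.0, 3.0, 7.0, 0.0])


@pytest.fixture(scope="session")
def small_recording():
    cfg = SynthConfig(n_samples=2048, n_peaks=8, min_separation=100, edge_margin=60, seed=7)
    return generate(cfg)


@pytest.fixture(scope="session")
def separable():
    return make_separable_fixture(1)
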