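import numpy as np
import pytest

from toothtrace.synthetic import SyntheticIsoscapeSpec, generate_isoscape


@pytest.fixture(scope="session")
def world():
    """Default synthetic study area (fixed seed)."""
    return generate_isoscape(SyntheticIsoscapeSpec(), seed=1)


@pytest.fixture(scope="session")
def flat_world():
    """Noise-free study area: every cell equals its zone mean."""
    return generate_isoscape(SyntheticIsoscapeSpec(noise_sd=0.0), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230303)
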