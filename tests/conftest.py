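import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def topo4():
    from somnirl.synth import make_topographies
    return make_topographies(4, seed=7)


@pytest.fixture(scope="session")
def small_recordings():
    """Tiny balanced synthetic dataset (4 states x 2 recordings x 12 s)."""
    from somnirl.synth import GeneratorConfig, make_dataset
    return make_dataset(2, GeneratorConfig(duration_s=12.0), seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
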