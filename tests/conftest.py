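import numpy as np
import pytest
from hypothesis import settings

from palaeoveg.biomization import default_scheme

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from palaeoveg.synthetic import GeneratorConfig, make_drivers, simulate_core


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def small_cfg():
    """A short record (350 kyr at 0.7-kyr sampling) for fast chain tests."""
    return GeneratorConfig(span=350.0, seed=11)


@pytest.fixture(scope="session")
def small_core(small_cfg, scheme):
    drivers = make_drivers(small_cfg)
    core, truth = simulate_core(small_cfg, drivers, scheme=scheme)
    return core, truth, drivers


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
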