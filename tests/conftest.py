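import numpy as np
import pytest

import spectrafuse as sf


@pytest.fixture(scope="session")
def small_blocks():
    """Plain 5-class paired blocks at reduced grid size (fast, study n)."""
    return sf.simulate_blocks(seed=7, ftmir_n=60, nir_n=80)


@pytest.fixture(scope="session")
def scenario():
    """Complementary-information scenario at reduced grid size, study n=196."""
    (mir, nir), masks = sf.make_complementary_scenario(seed=1, ftmir_n=100, nir_n=100)
    return mir, nir, masks


@pytest.fixture(scope="session")
def scenario_split(scenario):
    mir, nir, _ = scenario
    return sf.split_by_class((mir, nir))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
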