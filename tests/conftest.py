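import logging

import pytest

from cvdmicrosim import SyntheticSpec, generate_fixture, generate_parameter_set

logging.getLogger("cvdmicrosim").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def ps_full():
    """Full 24-cohort India-like synthetic parameter set."""
    return generate_parameter_set(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def ps_small():
    """Four-cohort fixture (all 20-29 bands) for fast structural tests."""
    return generate_fixture(4, seed=2)


@pytest.fixture(scope="session")
def ps_one():
    """Single-cohort fixture."""
    return generate_fixture(1, seed=3)
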