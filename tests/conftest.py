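import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20250924)


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic city + cohort, shared across tests."""
    from urbanfrail.simulate import simulate_study

    return simulate_study(42)
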