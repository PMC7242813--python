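import numpy as np
import pytest

from aplysia_swallow.synth import generate_session


@pytest.fixture(scope="session")
def loaded_session():
    """One mid-sized loaded session shared by read-only tests."""
    return generate_session(5, "loaded", seed=11)


@pytest.fixture(scope="session")
def unloaded_session():
    return generate_session(5, "unloaded", seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
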