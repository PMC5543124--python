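import numpy as np
import pytest

from conductionscan import PhantomSpec, ShellSpec, generate_phantom, generate_shell_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """The full-resolution two-chamber phantom (seed 42)."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def coarse_phantom():
    """Half-resolution phantom for fast tissue-scale tests."""
    return generate_phantom(PhantomSpec().coarse())


@pytest.fixture(scope="session")
def shell_phantom():
    """Default helical-ramp cylindrical shell (+60 to -60 degrees)."""
    return generate_shell_phantom(ShellSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
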