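import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from sinuslms.phantom import default_fixture_suite


@pytest.fixture(scope="session")
def small_suite():
    """Default fixture suite on the fast small canvas (noiseless)."""
    return default_fixture_suite(11, n_slices=10, height=112, width=128)


@pytest.fixture(scope="session")
def full_suite():
    """Default fixture suite at the full 448x512 canvas (noiseless)."""
    return default_fixture_suite(7)


@pytest.fixture(scope="session")
def noisy_full_suite():
    """Full-canvas suite with 20 HU additive Gaussian noise."""
    return default_fixture_suite(7, noise_sd=20.0)
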