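import numpy as np
import pytest

from maacs.phantom import PhantomConfig, degenerate_config, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def default_suite():
    """One default-conditions phantom suite (10 atlases, 128x128)."""
    return generate(PhantomConfig(seed=0))


@pytest.fixture(scope="session")
def small_suite():
    """A small, fast suite for pipeline-level tests."""
    return generate(PhantomConfig(seed=7, n_atlases=4))


@pytest.fixture(scope="session")
def degenerate_suite():
    """Zero-perturbation, zero-noise suite: atlas geometry == target geometry."""
    return generate(degenerate_config(seed=0))
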