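import numpy as np
import pytest

from prime3d2d.fixtures import FixtureSpec, make_template_library, make_toy_complex


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_spec():
    return FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def toy_complex(toy_spec):
    """(ComplexStructure, SecondaryStructure) with planted interface."""
    return make_toy_complex(toy_spec)


@pytest.fixture(scope="session")
def toy_library(toy_spec):
    """(Target, [TemplateEntry]) with 3 entries above and 3 below the cutoff."""
    return make_template_library(toy_spec)
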