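import numpy as np
import pytest
from hypothesis import settings

import debtraits as dt

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_params():
    """The six fixed reptile-like parameter sets."""
    return dt.reference_fixture()


@pytest.fixture(scope="session")
def fixture_table(fixture_params):
    """Trait table of the reference fixture at f=1, 20 degC."""
    return dt.build_trait_table(fixture_params)


@pytest.fixture(scope="session")
def default_family():
    """The default synthetic family: n=300, 3 decades of zoom, 0.1-dex scatter."""
    return dt.generate_parameter_table(dt.SyntheticConfig())


@pytest.fixture(scope="session")
def default_family_table(default_family):
    return dt.build_trait_table(default_family)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)
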