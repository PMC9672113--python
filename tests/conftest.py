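import numpy as np
import pytest

import penguinflow as pf


@pytest.fixture(scope="session")
def adelie_config():
    return pf.default_config("adelie")


@pytest.fixture(scope="session")
def adelie_deployment(adelie_config):
    """One default Adelie deployment, shared read-only across tests."""
    return pf.generate_deployment(adelie_config, "S1_I000", "S1", "S1_I000_T0")


@pytest.fixture(scope="session")
def adelie_frame(adelie_deployment):
    return pf.build_features(adelie_deployment)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
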