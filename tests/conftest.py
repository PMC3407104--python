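import numpy as np
import pytest

from ifnpkpd import reference


@pytest.fixture(scope="session")
def gfp_params():
    return reference.ifngfp_parameters()


@pytest.fixture(scope="session")
def apo_params():
    return reference.ifngfpapo_parameters()


@pytest.fixture(scope="session")
def both_params():
    return reference.reference_parameters()


@pytest.fixture(scope="session")
def fine_grid():
    return np.linspace(0.0, 48.0, 961)
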