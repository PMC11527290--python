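import numpy as np
import pytest

from sleepswitch.model import simulate
from sleepswitch.params import ModelParameters
from sleepswitch.pipelines import build_reduced_library


@pytest.fixture(scope="session")
def reduced_library():
    """72-combination infant-region library shared by the fitting tests.

    Built once per session (~2 min of simulation)."""
    return build_reduced_library()


@pytest.fixture(scope="session")
def adult_result():
    """Adult-default simulation under the standard 28+35-day protocol."""
    return simulate(ModelParameters())


@pytest.fixture(scope="session")
def infant_result():
    """A representative polyphasic infant-region simulation."""
    return simulate(ModelParameters().with_combo(8.1, 10.0, -3.0, 0.95))
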