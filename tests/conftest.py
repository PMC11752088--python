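import numpy as np
import pytest

from sandicortex import build_default_scheme
from sandicortex.dictfit import FitConfig, build_dictionary


@pytest.fixture(scope="session")
def scheme():
    return build_default_scheme()


@pytest.fixture(scope="session")
def default_dictionary(scheme):
    return build_dictionary(scheme, FitConfig())


@pytest.fixture(scope="session")
def pipeline_dictionary(scheme):
    return build_dictionary(scheme, FitConfig.pipeline_default())


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
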