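import numpy as np
import pytest
from hypothesis import settings

import hazegrid as hg

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def atm() -> hg.AtmosphericFunctions:
    return hg.AtmosphericFunctions()


@pytest.fixture(scope="session")
def lut(atm) -> hg.LookupTable:
    return hg.build_lookup_table(atm)


@pytest.fixture
def spec20() -> hg.GridSpec:
    return hg.GridSpec(20, 20)


@pytest.fixture
def full_weights_3x3():
    return hg.build_weights(np.ones((3, 3), dtype=bool), scheme="rook",
                            standardization="binary")
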