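import numpy as np
import pytest

from bgbeta.builders import complete_tables


@pytest.fixture(scope="session")
def tables():
    return complete_tables()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
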