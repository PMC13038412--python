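import warnings

import numpy as np
import pytest

from prxkit.errors import IdentifiabilityWarning


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(autouse=True)
def _quiet_identifiability():
    """Weak-identifiability warnings are expected in stress cases; keep the
    log readable while still letting tests assert on them explicitly."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", IdentifiabilityWarning)
        yield
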