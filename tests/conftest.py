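import logging

import numpy as np
import pytest

from sirna_escape import PAPER_THETA, RateSet

logging.getLogger("sirna_escape").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def theta() -> RateSet:
    """The default rate set used throughout the worked examples."""
    return PAPER_THETA


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
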