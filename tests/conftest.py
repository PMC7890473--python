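import numpy as np
import pytest

#: the 10-value demonstration series and its known 8-pattern encoding
DEMO_SERIES = [34, 3, 5, 23, 247, 234, 12, 1, 2, 3]
DEMO_PATTERNS = [
    (2, 0, 1),
    (0, 1, 2),
    (0, 1, 2),
    (0, 2, 1),
    (2, 1, 0),
    (2, 1, 0),
    (2, 0, 1),
    (0, 1, 2),
]

#: the published legitimate-transition table for D=3, tau=1
TABLE1 = {
    (0, 1, 2): {(0, 1, 2), (0, 2, 1), (1, 2, 0)},
    (0, 2, 1): {(1, 0, 2), (2, 0, 1), (2, 1, 0)},
    (1, 0, 2): {(0, 1, 2), (0, 2, 1), (1, 2, 0)},
    (1, 2, 0): {(1, 0, 2), (2, 0, 1), (2, 1, 0)},
    (2, 0, 1): {(0, 1, 2), (0, 2, 1), (1, 2, 0)},
    (2, 1, 0): {(1, 0, 2), (2, 0, 1), (2, 1, 0)},
}


@pytest.fixture
def demo_series():
    return list(DEMO_SERIES)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
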