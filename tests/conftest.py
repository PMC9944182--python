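import numpy as np
import pytest

from switchgrow import SwitchRates

# fitted point estimates per diet x instar cell, switches/hour
RATE_PAIRS = {
    ("diet", 4): (10.25, 4.93),
    ("tobacco", 4): (16.21, 10.19),
    ("devilsclaw", 4): (56.22, 24.36),
    ("diet", 5): (16.85, 11.05),
    ("tobacco", 5): (10.7, 12.63),
    ("devilsclaw", 5): (59.43, 37.99),
}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def rates_d4():
    return SwitchRates(10.25, 4.93)


@pytest.fixture
def rates_d5():
    return SwitchRates(16.85, 11.05)


@pytest.fixture(params=sorted(RATE_PAIRS), ids=lambda k: f"{k[0]}{k[1]}")
def table_rates(request):
    lf, ln = RATE_PAIRS[request.param]
    return SwitchRates(lf, ln)
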