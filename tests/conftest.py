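import pytest

from tokenward import RandomStream, default_scenario
from tokenward.config import PriceList


@pytest.fixture
def cfg():
    """The reference scenario (3 wards x 40 beds, 3x3 patterns)."""
    return default_scenario()


@pytest.fixture
def rng():
    return RandomStream(12345)


@pytest.fixture
def flat_prices(cfg):
    """Price-list factory: the same price for every pattern."""

    def make(value: float, day: int = 0) -> PriceList:
        return PriceList({pat: float(value) for pat in cfg.patterns()}, effective_day=day)

    return make
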