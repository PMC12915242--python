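import pytest

from waxmrm.species import ChainKind, ChainMoiety


@pytest.fixture
def fa():
    return lambda c, d=0: ChainMoiety(ChainKind.FA, c, d)


@pytest.fixture
def fal():
    return lambda c, d=0: ChainMoiety(ChainKind.FAL, c, d)


@pytest.fixture
def dfa():
    return lambda c, d=0: ChainMoiety(ChainKind.DIOL_FA, c, d)


@pytest.fixture
def woh():
    return lambda c, d=0: ChainMoiety(ChainKind.WOH_FA, c, d)
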