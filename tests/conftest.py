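import pytest

from crctdesign import EffectSpec, TestParams


@pytest.fixture
def t80() -> TestParams:
    return TestParams(alpha=0.05, power=0.80)


@pytest.fixture
def t90() -> TestParams:
    return TestParams(alpha=0.05, power=0.90)


@pytest.fixture
def breastfeeding() -> EffectSpec:
    """The 40% vs 50% breastfeeding-initiation effect."""
    return EffectSpec.binary(0.4, 0.5)
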