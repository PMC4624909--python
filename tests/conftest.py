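import pytest

from ednasens import (BIGHEAD_CARP, SILVER_CARP, ExtractionModel,
                      SamplingProtocol)


@pytest.fixture
def bighead():
    return BIGHEAD_CARP


@pytest.fixture
def silver():
    return SILVER_CARP


@pytest.fixture
def baseline():
    return SamplingProtocol.baseline()


@pytest.fixture
def extraction():
    return ExtractionModel()
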