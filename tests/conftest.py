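import pytest

from bnperturb import fixture


@pytest.fixture
def oscillator():
    return fixture("oscillator")


@pytest.fixture
def oscillator_plus_source():
    return fixture("oscillator_plus_source")


@pytest.fixture
def mutual_inhibition():
    return fixture("mutual_inhibition")


@pytest.fixture
def three_cycle():
    return fixture("three_cycle")


@pytest.fixture
def all_constant():
    return fixture("all_constant")


@pytest.fixture(params=[
    "oscillator",
    "oscillator_plus_source",
    "mutual_inhibition",
    "three_cycle",
    "all_constant",
])
def any_fixture(request):
    return fixture(request.param)
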