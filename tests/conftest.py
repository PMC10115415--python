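import pytest

from cyp33switch import build_network, default_parameter_set


@pytest.fixture(scope="session")
def params():
    return default_parameter_set()


@pytest.fixture(scope="session")
def net(params):
    return build_network(params)
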