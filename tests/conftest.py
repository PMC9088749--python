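import pytest

from saffronms.compounds import default_registry, fingerprint_table


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def fingerprint(registry):
    return fingerprint_table(registry)
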