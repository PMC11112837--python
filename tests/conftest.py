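import pytest

from drscreen import filter_gradable, oslo_fixture


@pytest.fixture(scope="session")
def oslo_records():
    return oslo_fixture()


@pytest.fixture(scope="session")
def oslo_gradable(oslo_records):
    return filter_gradable(oslo_records)
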