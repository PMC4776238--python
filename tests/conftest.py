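import pytest

from oncopanel import generate_kb_fixture, synthetic_panel


@pytest.fixture(scope="session")
def panel():
    return synthetic_panel()


@pytest.fixture(scope="session")
def kb():
    return generate_kb_fixture()
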