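import pytest

from hlhpanel.panel import default_panel


@pytest.fixture(scope="session")
def panel():
    """The default 12-gene panel with its synthetic tiling geometry."""
    return default_panel()


@pytest.fixture(scope="session")
def genes(panel):
    return panel[0]


@pytest.fixture(scope="session")
def amplicons(panel):
    return panel[1]
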