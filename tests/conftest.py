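import pytest

from gsl4d import library4d


@pytest.fixture(scope="session")
def serum_lib():
    return library4d.serum_fixture()


@pytest.fixture(scope="session")
def fixture_names(serum_lib):
    """All parseable species names of the serum fixture."""
    return [e.name for e in serum_lib if e.species is not None]
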