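import pytest

from circrca import make_fixture_loci


@pytest.fixture(scope="session")
def fixture_set():
    """The six-locus fixture panel at a fixed seed."""
    return make_fixture_loci(seed=1)


@pytest.fixture(scope="session")
def cnot2(fixture_set):
    return fixture_set["CNOT2"]


@pytest.fixture(scope="session")
def mapk9(fixture_set):
    return fixture_set["MAPK9"]
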