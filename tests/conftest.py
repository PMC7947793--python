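import pytest

from scaadock.fixtures import make_mock_receptor, make_planted_complex


@pytest.fixture(scope="session")
def mock_receptor():
    return make_mock_receptor(seed=0)


@pytest.fixture(scope="session")
def planted():
    """The planted-pose complex used across docking tests (built once).

    The triad is the SCAA translation of a known TCR-bound antigen triad
    (Asn-Val-Arg -> Gln-Val-His); the charged histidine gives the mock
    landscape realistic electrostatic structure.
    """
    return make_planted_complex(("Q", "V", "H"), seed=0)
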