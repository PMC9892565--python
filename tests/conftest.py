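import pytest

from rendr import simulate as sim
from rendr import thermo


@pytest.fixture(scope="session")
def ribozyme():
    """Synthetic full-length ribozyme stand-in (420 nt -> 419 split sites)."""
    return sim.synthetic_ribozyme()


@pytest.fixture(scope="session")
def cds():
    """Synthetic reporter CDS with a U-initial codon at position 66."""
    return sim.synthetic_cds()


@pytest.fixture(scope="session")
def input_rna():
    """Synthetic 650-nt RNA input transcript."""
    return sim.synthetic_input()


@pytest.fixture(scope="session")
def nn_backend():
    return thermo.NearestNeighborBackend()


@pytest.fixture(scope="session")
def vienna_backend():
    return thermo.ViennaRNABackend()
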