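import numpy as np
import pytest

from hotseq.fasta_io import ProteinChain, load_example_chains
from hotseq.properties import load_default_properties


@pytest.fixture(scope="session")
def table():
    return load_default_properties()


@pytest.fixture(scope="session")
def example_chains():
    """The bundled antibody heavy/light chain pair."""
    return load_example_chains()


@pytest.fixture()
def tiny_chain():
    return ProteinChain(chain_id="c1", sequence="ACDEFGHIKL")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
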