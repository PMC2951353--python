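import pytest

from igtls.data import architecture
from igtls.synth import DonorSimParams, simulate_parent, simulate_pseudogene_db


@pytest.fixture(scope="session")
def parent():
    return simulate_parent(400, seed=101)


@pytest.fixture(scope="session")
def donor_db(parent):
    return simulate_pseudogene_db(parent, DonorSimParams(n_donors=6, divergence=0.04, seed=202))


@pytest.fixture(scope="session")
def pqts_arch():
    return architecture("pqts")


@pytest.fixture(scope="session")
def pqto_arch():
    return architecture("pqto")
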