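import pytest

from grkin.ligands import default_rates, get_ligand


@pytest.fixture(scope="session")
def rates():
    return default_rates()


@pytest.fixture(scope="session")
def dex():
    return get_ligand("dexamethasone").params


@pytest.fixture(scope="session")
def cortisol():
    return get_ligand("cortisol").params
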