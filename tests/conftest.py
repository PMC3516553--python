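import pytest

from autozygome import SimConfig, build_family_pedigree, simulate_family


@pytest.fixture(scope="session")
def family_pedigree():
    return build_family_pedigree()


@pytest.fixture(scope="session")
def family_sim():
    """One simulated index-family dataset shared across tests."""
    return simulate_family(SimConfig(seed=11))
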