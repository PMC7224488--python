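import pytest

from mitoarch import load_reference_genome
from mitoarch.synthetic_mitogenome import default_spec, generate_mitogenome


@pytest.fixture(scope="session")
def dh_genome():
    """Bundled published D. houi annotation (features only, no sequence)."""
    return load_reference_genome("DH")


@pytest.fixture(scope="session")
def sim_result():
    """One deterministic default synthetic genome, shared across tests."""
    return generate_mitogenome(default_spec(seed=20240214))


@pytest.fixture(scope="session")
def sim_genome(sim_result):
    return sim_result.genome
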