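import numpy as np
import pytest

from trappkit.chem import enumerate_targeted_adducts
from trappkit.digest import digest_database, generate_decoys
from trappkit.search import SearchConfig, build_candidate_index
from trappkit.simulate import generate_proteome


@pytest.fixture(scope="session")
def mono_adducts():
    """The six single-nucleotide 4tU adducts."""
    return enumerate_targeted_adducts(max_len=1, alphabet=("4tU",))


@pytest.fixture(scope="session")
def small_proteome():
    return generate_proteome(20, mean_length=120, seed=99)


@pytest.fixture(scope="session")
def search_db(small_proteome):
    """Target + reversed-decoy peptide candidates for the small proteome."""
    return digest_database(small_proteome + generate_decoys(small_proteome))


@pytest.fixture(scope="session")
def search_index(search_db, mono_adducts):
    return build_candidate_index(search_db, mono_adducts)


@pytest.fixture(scope="session")
def search_config():
    return SearchConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
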