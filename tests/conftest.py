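import numpy as np
import pytest

from microcensus import CommunitySpec, build_community
from microcensus.primers import load_primer_pairs


@pytest.fixture(scope="session")
def primer_pair():
    """The packaged 515F/806R-style example pair."""
    return load_primer_pairs()[0]


@pytest.fixture(scope="session")
def small_community():
    """A small paired community used by several recovery tests."""
    spec = CommunitySpec(
        n_genomes=10,
        n_ultrasmall=3,
        genome_length_bp=(8_000, 20_000),
        seq_bases_bulk=4e7,
        seq_bases_concentrate=4e6,
        seed=42,
    )
    return build_community(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_517)
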