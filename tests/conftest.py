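import numpy as np
import pytest

from enhmotif import EnhancerSequence, GenomicInterval, demo_motif_library
from enhmotif.synthetic import random_sequences


@pytest.fixture(scope="session")
def library():
    return demo_motif_library()


@pytest.fixture(scope="session")
def library_by_id(library):
    return {m.motif_id: m for m in library}


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_enhancer(seq: str, name: str = "e1", group: str = "Q") -> EnhancerSequence:
    return EnhancerSequence(
        GenomicInterval("chr1", 0, len(seq), name, group), seq
    )


@pytest.fixture
def enhancer_factory():
    return make_enhancer


def plant(seq: str, word: str, offset: int) -> str:
    return seq[:offset] + word + seq[offset + len(word):]


@pytest.fixture(scope="session")
def background_pool():
    """Shared pool of plain background sequences for enrichment tests."""
    rng = np.random.default_rng(555)
    return random_sequences(rng, 1200, 200)
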