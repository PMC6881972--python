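import numpy as np
import pytest

from afmeta.binning import build_genome_bins
from afmeta.simulate import synth_genomes


@pytest.fixture
def rng():
    return np.random.default_rng(20230915)


def random_sequence(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture(scope="session")
def small_panel():
    """Six synthetic genomes spanning GC 0.3-0.7, 5 kb each."""
    return synth_genomes(
        6, (0.3, 0.7), length=5000, order=1, rng=np.random.default_rng(7)
    )


@pytest.fixture(scope="session")
def small_binset(small_panel):
    return build_genome_bins(small_panel, C=2, order=1)
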