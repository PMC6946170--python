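import numpy as np
import pytest

from gynotype import GenomeSpec, ReadModel, scaled_genome
from gynotype.genome import ChromosomeSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_genome():
    """Six 8-Mb chromosomes: the scale used for simulation studies."""
    return scaled_genome(8_000_000)


@pytest.fixture
def tiny_genome():
    """Two short chromosomes for fast unit tests."""
    return GenomeSpec(chromosomes=[ChromosomeSpec("c1", 2_000_000),
                                   ChromosomeSpec("cX", 2_000_000, is_X=True)],
                      snp_spacing=500.0)


@pytest.fixture
def single_chrom_genome():
    return GenomeSpec(chromosomes=[ChromosomeSpec("chr1", 5_000_000)])


@pytest.fixture
def read_model():
    return ReadModel(mean_depth=30.0, overdispersion_rho=0.05)
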