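import numpy as np
import pytest

from longamp import GenomeSpec, default_designs, generate_genome


@pytest.fixture(scope="session")
def designs():
    return default_designs()


@pytest.fixture(scope="session")
def variant_genome():
    """10 operons, 3 ITS variants, single 16S variant."""
    return generate_genome(GenomeSpec(
        name="Varia_testis_V1", n_operons=10, n_its_variants=3,
        genome_size=60_000, seed=11))


@pytest.fixture(scope="session")
def tm7x_like_genome():
    """Non-contiguous operon: ITS 450 bp + 4,570 bp insertion, so the long
    design's product is 7,069 bp (over the 3,500 bp ceiling)."""
    return generate_genome(GenomeSpec(
        name="Nanosynbacter_like_N1", n_operons=1, its_length=450,
        non_contiguous=True, insertion_length=4_570,
        genome_size=20_000, seed=13))


@pytest.fixture(scope="session")
def small_community():
    """Three taxa with distinct operon architectures (session-scoped; used
    read-only by profiling/diversity tests)."""
    specs = [
        GenomeSpec(name="Alpha_one_A1", n_operons=4, n_its_variants=2,
                   genome_size=45_000, seed=21),
        GenomeSpec(name="Beta_two_B1", n_operons=3, n_its_variants=1,
                   genome_size=45_000, seed=22),
        GenomeSpec(name="Gamma_three_C1", n_operons=5, n_its_variants=3,
                   genome_size=50_000, seed=23),
    ]
    return {s.name: generate_genome(s) for s in specs}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
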