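import pytest

from magbench import gen_genomes, gen_taxonomy


@pytest.fixture(scope="session")
def groups():
    """Three validated synthetic replicate groups with triplets built."""
    return gen_taxonomy(3, seed=11)


@pytest.fixture(scope="session")
def group_a(groups):
    return groups[0]


@pytest.fixture(scope="session")
def small_genomes(group_a):
    """Test-scale genomes (20-60 kb) for group A."""
    return gen_genomes(group_a, length_range=(20_000, 60_000), seed=4)
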