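import pytest

from mthet.reference import load_pathogenicity, load_rcrs_regions, load_toy_regions
from mthet.simulate import random_genome


@pytest.fixture(scope="session")
def toy_genome():
    return random_genome(2000, seed=11, name="toy")


@pytest.fixture(scope="session")
def mt_genome():
    """Full-length synthetic stand-in for the mitochondrial reference."""
    return random_genome(16569, seed=1)


@pytest.fixture(scope="session")
def toy_regions():
    return load_toy_regions()


@pytest.fixture(scope="session")
def rcrs_regions():
    return load_rcrs_regions()


@pytest.fixture(scope="session")
def ptable():
    return load_pathogenicity()
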