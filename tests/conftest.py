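import numpy as np
import pytest

from intronret.il18r1 import build_demo_locus, load_primers, load_query
from intronret.gene_models import build_intron_retained, build_spliced
from intronret.synthetic_data import LocusParams, generate_locus


@pytest.fixture(scope="session")
def demo_locus():
    return build_demo_locus(seed=0)


@pytest.fixture(scope="session")
def demo_builds(demo_locus):
    spliced = build_spliced(demo_locus.gene, demo_locus.genome)
    retained = build_intron_retained(demo_locus.gene, demo_locus.genome, 8)
    return spliced, retained


@pytest.fixture(scope="session")
def demo_primers():
    return load_primers()


@pytest.fixture(scope="session")
def query_record():
    return load_query()


@pytest.fixture(scope="session")
def basic_locus():
    """A small default synthetic locus (phase 1, 5-codon novel tail)."""
    return generate_locus(LocusParams(), seed=101)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
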