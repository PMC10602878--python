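import numpy as np
import pytest

from genedomains.accessibility import GeneAnnotation
from genedomains.contact_matrix import (ContactMatrix, FragmentMap,
                                        build_fragment_map,
                                        observed_over_expected)
from genedomains.synthetic_data import recovery_dataset


@pytest.fixture
def toy_map():
    """Three 100 bp fragments on a 300 bp chromosome."""
    return build_fragment_map(300, [100, 200])


@pytest.fixture
def uniform_map():
    """Forty equal 100 bp fragments."""
    return build_fragment_map(4000, list(range(100, 4000, 100)))


def random_contact_matrix(fragment_map: FragmentMap, rng,
                          density: float = 0.6,
                          integer: bool = False) -> ContactMatrix:
    n = fragment_map.n_fragments
    dense = rng.random((n, n)) * 10
    if integer:
        dense = np.floor(dense)
    dense = np.triu(dense)
    dense[rng.random((n, n)) > density] = 0
    dense = np.triu(dense) + np.triu(dense, k=1).T
    return ContactMatrix.from_dense(fragment_map, dense)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def recovery_data():
    """Tuned synthetic dataset with recoverable per-gene domain strength."""
    return recovery_dataset(seed=1)


@pytest.fixture(scope="session")
def recovery_oe(recovery_data):
    from genedomains.contact_matrix import kr_balance

    balanced = kr_balance(recovery_data["matrix"])
    return observed_over_expected(balanced)


def make_gene(start, end, strand="+", gene_id="g", chrom="chr1"):
    return GeneAnnotation(gene_id, chrom, start, end, strand)
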