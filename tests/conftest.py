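import numpy as np
import pytest

from seclipid.model import (DomainAnnotation, DomainKind, Gene, GeneCluster,
                            load_catalog)


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


def make_cluster(kinds, cluster_id="c1", organism="Testus organismus X1",
                 split=None):
    """Build a cluster from a flat list of domain-kind names.

    ``split`` optionally gives gene sizes; by default all domains sit on one
    gene.
    """
    kinds = [DomainKind(k) for k in kinds]
    sizes = split or [len(kinds)]
    assert sum(sizes) == len(kinds)
    genes, pos = [], 0
    for gi, size in enumerate(sizes, start=1):
        domains = tuple(DomainAnnotation(k, j + 1)
                        for j, k in enumerate(kinds[pos:pos + size]))
        genes.append(Gene(locus_id=f"{cluster_id}_g{gi}", domains=domains))
        pos += size
    return GeneCluster(cluster_id=cluster_id, organism=organism,
                       genes=tuple(genes))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
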