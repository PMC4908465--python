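import numpy as np
import pytest

from hybridzone.core import GenotypeMatrix
from hybridzone.synthetic import generate_parental_frequencies


def make_genotypes(rows, loci=None, ids=None, metadata=None):
    """Build a GenotypeMatrix from a list of per-individual locus pairs,
    e.g. [[(100, 102), None], ...] with None meaning missing."""
    n = len(rows)
    L = len(rows[0])
    loci = loci or [f"L{j + 1}" for j in range(L)]
    ids = ids or [f"i{k + 1}" for k in range(n)]
    alleles = np.full((n, L, 2), -9, dtype=np.int64)
    for i, row in enumerate(rows):
        for j, pair in enumerate(row):
            if pair is not None:
                alleles[i, j] = pair
    return GenotypeMatrix(ids, loci, alleles, metadata)


@pytest.fixture(scope="session")
def diagnostic_pools():
    """Two pools fixed for alternate alleles at every locus (F_ST = 1)."""
    return generate_parental_frequencies(
        n_loci=8, alleles_per_locus=2, divergence=1.0, seed=11
    )


@pytest.fixture(scope="session")
def divergent_pools():
    """Strongly but not fully diverged pools, 17 microsatellite-like loci."""
    return generate_parental_frequencies(
        n_loci=17, alleles_per_locus=8, divergence=0.5, seed=1
    )
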