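import numpy as np
import pytest

from ssrpop.genodata import GenotypeMatrix
from ssrpop import synthetic_data as sd


def make_matrix(cells, individuals=None, loci=None):
    """Build a GenotypeMatrix from a nested list of (a, b) or None cells."""
    n = len(cells)
    L = len(cells[0])
    arr = np.full((n, L, 2), -1, dtype=np.int64)
    for i, row in enumerate(cells):
        for j, cell in enumerate(row):
            if cell is not None:
                arr[i, j] = cell
    individuals = individuals or [f"S{i + 1}" for i in range(n)]
    loci = loci or [f"L{j + 1}" for j in range(L)]
    return GenotypeMatrix(individuals, loci, arr)


@pytest.fixture(scope="session")
def fixtures():
    return sd.fixture_panels(seed=0)


@pytest.fixture(scope="session")
def hand_locus():
    """Three individuals, one locus: (150,150), (150,152), (152,154)."""
    return make_matrix([[(150, 150)], [(150, 152)], [(152, 154)]])


def random_panel(rng, n_ind=None, n_loci=None, n_alleles=None, p_missing=0.1):
    """Small random panel for oracle-equivalence sweeps."""
    n_ind = n_ind or rng.integers(2, 11)
    n_loci = n_loci or rng.integers(1, 4)
    n_alleles = n_alleles or rng.integers(1, 5)
    arr = 150 + 2 * rng.integers(0, n_alleles, size=(int(n_ind), int(n_loci), 2))
    miss = rng.random((int(n_ind), int(n_loci))) < p_missing
    # keep at least one call per locus
    for j in range(int(n_loci)):
        if miss[:, j].all():
            miss[0, j] = False
    arr[miss] = -1
    return GenotypeMatrix(
        [f"S{i}" for i in range(int(n_ind))],
        [f"L{j}" for j in range(int(n_loci))],
        arr,
    )
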