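import numpy as np
import pytest

from kinskew.genotypes import GenotypeMatrix
from kinskew.simdata import SimConfig, simulate_population


def make_matrix(rows, loci=None, groups=None):
    """Build a GenotypeMatrix from {id: [(a1, a2), ...]}."""
    ids = list(rows)
    n_loci = len(next(iter(rows.values())))
    loci = loci or [f"L{k}" for k in range(n_loci)]
    alleles = np.array([rows[i] for i in ids], dtype=np.int64)
    return GenotypeMatrix(ids, loci, alleles, groups)


def deme_fixture(n_demes, per_deme, L=13, A=None, own=1.0, other=0.02, seed=0):
    """Strongly separated demes: each nearly fixed for its own allele."""
    rng = np.random.default_rng(seed)
    A = A or n_demes
    g, ids, groups = [], [], {}
    for d in range(n_demes):
        p = np.full(A, other)
        p[d % A] = own
        p /= p.sum()
        for k in range(per_deme):
            ident = f"d{d}i{k}"
            ids.append(ident)
            groups[ident] = f"d{d}"
            g.append(np.sort(rng.choice(A, size=(L, 2), p=p) + 1, axis=1))
    return GenotypeMatrix(ids, [f"L{l}" for l in range(L)], np.stack(g), groups)


def hwe_matrix(freqs, n, seed=0, groups=None):
    """Draw n HWE genotypes from an (L, A) frequency array."""
    rng = np.random.default_rng(seed)
    L, A = freqs.shape
    g = np.zeros((n, L, 2), dtype=np.int64)
    for l in range(L):
        g[:, l, :] = rng.choice(A, size=(n, 2), p=freqs[l]) + 1
    return GenotypeMatrix([f"i{k}" for k in range(n)],
                          [f"L{l}" for l in range(L)],
                          np.sort(g, axis=2), groups)


@pytest.fixture(scope="session")
def small_population():
    """Default 7-group population, 3 seasons (kin-structured, with pups)."""
    return simulate_population(SimConfig(seed=1, n_seasons=3))


@pytest.fixture(scope="session")
def two_season_population():
    """Population whose pup candidates contain no aged-up siblings."""
    return simulate_population(SimConfig(seed=3, n_seasons=2))
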