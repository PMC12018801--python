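import numpy as np
import pandas as pd
import pytest

from dynaqtl.genmap import GeneticMap
from dynaqtl.haplotypes import reconstruct_haplotypes
from dynaqtl.simulate import (
    simulate_founder_genomes,
    simulate_magic_rils,
    uniform_marker_map,
)


@pytest.fixture(scope="session")
def small_map() -> GeneticMap:
    return uniform_marker_map(n_chromosomes=2, markers_per_chromosome=60)


@pytest.fixture(scope="session")
def panel(small_map):
    return simulate_founder_genomes(8, small_map, seed=11)


@pytest.fixture(scope="session")
def rils_and_mosaics(panel):
    return simulate_magic_rils(
        panel, n_rils=150, genotyping_error=0.002, missing_rate=0.02, seed=12
    )


@pytest.fixture(scope="session")
def hap_probs(panel, rils_and_mosaics):
    rils, _ = rils_and_mosaics
    return reconstruct_haplotypes(rils, panel, compute_viterbi=True)


@pytest.fixture(scope="session")
def true_founder_matrix(small_map, rils_and_mosaics):
    """True founder index per RIL per marker, from the recorded mosaics."""
    _, mosaics = rils_and_mosaics
    cols = []
    for c in small_map.chromosomes:
        bp = small_map.chrom_view(c)["bp"].to_numpy(dtype=float)
        cols.append(np.stack([m.chromosomes[c].founder_at(bp) for m in mosaics]))
    return np.concatenate(cols, axis=1)


def enumerate_posterior(geno_row, founder_alleles, cm, error_rate, lam):
    """Exhaustive sum-product posterior over all founder paths (oracle).

    Brute-force enumeration of K^M paths; tractable only for tiny
    instances, independent of the forward-backward implementation.
    """
    from itertools import product

    from dynaqtl.haplotypes import transition_matrix

    n_f, m = founder_alleles.shape
    trans = [transition_matrix(cm[j + 1] - cm[j], n_f, lam) for j in range(m - 1)]

    def emit(j, f):
        o = geno_row[j]
        if o in (-1, 2):
            return 1.0
        return 1.0 - error_rate if o == founder_alleles[f, j] else error_rate

    post = np.zeros((m, n_f))
    total = 0.0
    for path in product(range(n_f), repeat=m):
        w = 1.0 / n_f * emit(0, path[0])
        for j in range(1, m):
            w *= trans[j - 1][path[j - 1], path[j]] * emit(j, path[j])
        total += w
        for j in range(m):
            post[j, path[j]] += w
    return post / total


def haley_knott_lod(probs_marker, y):
    """Closed-form OLS Haley-Knott LOD at one marker (oracle)."""
    n = len(y)
    x = np.column_stack([np.ones(n), probs_marker[:, :-1]])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    rss1 = float(((y - x @ beta) ** 2).sum())
    rss0 = float(((y - y.mean()) ** 2).sum())
    return n / 2.0 * np.log10(rss0 / rss1)
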