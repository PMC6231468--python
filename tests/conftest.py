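import numpy as np
import pandas as pd
import pytest

from demosfs.genotypes import MISSING, GenotypeTable


def make_table(genotypes, locus_ids=None, localities=None, populations=None):
    """Small GenotypeTable from a dense dosage matrix (rows = individuals)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_ind, n_sites = g.shape
    if locus_ids is None:
        locus_ids = [f"loc{j}" for j in range(n_sites)]
    sites = pd.DataFrame({"locus_id": locus_ids, "pos": np.zeros(n_sites, dtype=int)})
    inds = [f"ind{i}" for i in range(n_ind)]
    locs = localities if localities is not None else ["L0"] * n_ind
    return GenotypeTable(g, inds, locs, sites, populations)


def random_table(rng, n_ind=8, n_sites=12, missing_rate=0.2, n_loci=None):
    """Random dosage table with missingness, for brute-force oracle checks."""
    g = rng.integers(0, 3, size=(n_ind, n_sites)).astype(np.int8)
    g[rng.random((n_ind, n_sites)) < missing_rate] = MISSING
    if n_loci:
        locus_ids = [f"loc{rng.integers(n_loci)}" for _ in range(n_sites)]
    else:
        locus_ids = None
    return make_table(g, locus_ids=locus_ids)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
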