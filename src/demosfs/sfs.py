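"""Folded pairwise joint site-frequency spectra.

A joint SFS for a population pair tallies SNPs by their allele-count
configuration (i copies in population A out of nA haplotypes, j of nB in
B). With no outgroup the ancestral state is unknown, so the spectrum is
*folded*: configurations (i, j) and (nA-i, nB-j) are pooled under the one
with the smaller pooled allele count (the minor allele). Sites genotyped
in fewer individuals than a per-population threshold are discarded, and
the remainder are projected down to the threshold sample size by
hypergeometric expectation, which removes all missing data while using
every retained site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import hypergeom

from .genotypes import GenotypeTable


class SFSError(RuntimeError):
    pass


def fold_configuration(i: int, j: int, n_a: int, n_b: int) -> tuple[int, int]:
    """Canonical (minor-allele) representative of configuration (i, j).

    If the pooled count i+j exceeds half the pooled sample size, the
    complementary configuration is returned; at exactly half, the
    lexicographically smaller of the two (a deterministic, involution-safe
    tie rule). Folding twice is the identity.
    """
    if not (0 <= i <= n_a and 0 <= j <= n_b):
        raise SFSError(f"configuration ({i},{j}) out of range for ({n_a},{n_b})")
    comp = (n_a - i, n_b - j)
    total = i + j
    half = (n_a + n_b) / 2
    if total > half:
        return comp
    if total == half:
        return min((i, j), comp)
    return (i, j)


_FOLD_CACHE: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}


def _fold_indices(n_a: int, n_b: int) -> tuple[np.ndarray, np.ndarray]:
    """Cached canonical-representative index grids for (n_a, n_b)."""
    key = (n_a, n_b)
    if key not in _FOLD_CACHE:
        fi = np.empty((n_a + 1, n_b + 1), dtype=np.intp)
        fj = np.empty_like(fi)
        for i in range(n_a + 1):
            for j in range(n_b + 1):
                fi[i, j], fj[i, j] = fold_configuration(i, j, n_a, n_b)
        _FOLD_CACHE[key] = (fi, fj)
    return _FOLD_CACHE[key]


def fold_grid(grid: np.ndarray) -> np.ndarray:
    """Fold an unfolded (nA+1)x(nB+1) mass grid onto canonical entries."""
    n_a = grid.shape[0] - 1
    n_b = grid.shape[1] - 1
    fi, fj = _fold_indices(n_a, n_b)
    out = np.zeros_like(grid, dtype=float)
    np.add.at(out, (fi.ravel(), fj.ravel()), grid.astype(float).ravel())
    return out


_MASK_CACHE: dict[tuple[int, int], np.ndarray] = {}


def folded_mask(n_a: int, n_b: int) -> np.ndarray:
    """Boolean mask, True = excluded from likelihood.

    Excluded entries are the non-canonical (folded-away) configurations
    and the monomorphic corner (0,0) (into which the doubly-fixed corner
    (nA,nB) folds).
    """
    key = (n_a, n_b)
    if key not in _MASK_CACHE:
        mask = np.ones((n_a + 1, n_b + 1), dtype=bool)
        for i in range(n_a + 1):
            for j in range(n_b + 1):
                if fold_configuration(i, j, n_a, n_b) == (i, j):
                    mask[i, j] = False
        mask[0, 0] = True
        _MASK_CACHE[key] = mask
    return _MASK_CACHE[key].copy()


def project_site(k_minor: int, n_from: int, n_to: int) -> np.ndarray:
    """Hypergeometric projection of an allele count to a smaller sample.

    Entry m is the probability that a without-replacement subsample of
    ``n_to`` haplotypes from ``n_from`` carrying ``k_minor`` copies
    contains exactly m copies: C(k,m) C(n_from-k, n_to-m) / C(n_from, n_to).
    """
    if n_to > n_from:
        raise SFSError(f"cannot project {n_from} haplotypes up to {n_to}")
    if not 0 <= k_minor <= n_from:
        raise SFSError("allele count out of range")
    m = np.arange(n_to + 1)
    return hypergeom.pmf(m, n_from, k_minor, n_to)


@dataclass
class FoldedJointSFS:
    """Folded joint SFS for one population pair.

    ``counts`` holds (possibly fractional, from projection) SNP mass on a
    full (nA+1)x(nB+1) grid; only unmasked (canonical, polymorphic)
    entries carry likelihood-relevant mass. ``mask`` is True on excluded
    entries.
    """

    pop_a: str
    pop_b: str
    n_a: int  # haplotype sample size of pop_a
    n_b: int
    counts: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.n_a + 1, self.n_b + 1):
            raise SFSError("counts grid does not match haplotype sizes")
        if self.mask is None:
            self.mask = folded_mask(self.n_a, self.n_b)

    @property
    def n_polymorphic(self) -> float:
        """Total unmasked SNP mass."""
        return float(self.counts[~self.mask].sum())

    def normalized(self) -> np.ndarray:
        """Probabilities over unmasked entries (masked entries zero)."""
        p = np.where(self.mask, 0.0, self.counts)
        tot = p.sum()
        if tot <= 0:
            raise SFSError("no polymorphic mass to normalize")
        return p / tot

    # -- plain-text serialization -----------------------------------------
    # line 1: "#pair <pop_a> <pop_b>", line 2: "#nhap <n_a> <n_b>",
    # then (nA+1) rows x (nB+1) tab-separated mass values.

    def to_text(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#pair\t{self.pop_a}\t{self.pop_b}\n")
            fh.write(f"#nhap\t{self.n_a}\t{self.n_b}\n")
            for row in self.counts:
                fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def from_text(cls, path: str | Path) -> "FoldedJointSFS":
        with open(path) as fh:
            header1 = fh.readline().split()
            header2 = fh.readline().split()
            if header1[0] != "#pair" or header2[0] != "#nhap":
                raise SFSError(f"{path} is not a folded joint SFS file")
            pop_a, pop_b = header1[1], header1[2]
            n_a, n_b = int(header2[1]), int(header2[2])
            counts = np.loadtxt(fh, ndmin=2)
        return cls(pop_a, pop_b, n_a, n_b, counts)


def build_pairwise_sfs(
    table: GenotypeTable,
    pop_a: str,
    pop_b: str,
    min_individuals: dict[str, int],
    seed: int | None = None,
) -> FoldedJointSFS:
    """Folded joint SFS for one population pair from a thinned SNP table.

    Sites genotyped in at least ``min_individuals[pop]`` individuals in
    *both* populations are kept; each kept site's alt-allele count is
    projected down to 2*min_individuals haplotypes per population by
    hypergeometric expectation (deterministic; ``seed`` is accepted for
    API symmetry but unused), the two projections combined as an outer
    product, and the mass folded onto minor-allele configurations.
    Fractional projected mass is kept fractional.
    """
    rows_a = table.individuals_in_population(pop_a)
    rows_b = table.individuals_in_population(pop_b)
    n_a = 2 * min_individuals[pop_a]
    n_b = 2 * min_individuals[pop_b]
    alt_a, hap_a = table.allele_counts(rows_a)
    alt_b, hap_b = table.allele_counts(rows_b)
    keep = (hap_a >= n_a) & (hap_b >= n_b)
    if not keep.any():
        raise SFSError(
            f"no site genotyped in >= {min_individuals[pop_a]}/{min_individuals[pop_b]} "
            f"individuals for pair ({pop_a},{pop_b})")
    grid = np.zeros((n_a + 1, n_b + 1))
    proj_cache: dict[tuple[int, int, int], np.ndarray] = {}

    def proj(k: int, n_from: int, n_to: int) -> np.ndarray:
        key = (k, n_from, n_to)
        if key not in proj_cache:
            proj_cache[key] = project_site(k, n_from, n_to)
        return proj_cache[key]

    for s in np.flatnonzero(keep):
        va = proj(int(alt_a[s]), int(hap_a[s]), n_a)
        vb = proj(int(alt_b[s]), int(hap_b[s]), n_b)
        grid += np.outer(va, vb)
    return FoldedJointSFS(pop_a, pop_b, n_a, n_b, fold_grid(grid))


def all_pairs(populations: list[str]) -> list[tuple[str, str]]:
    """Canonical ordering of the population pairs."""
    return [(a, b) for i, a in enumerate(populations) for b in populations[i + 1:]]
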