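"""Structured-coalescent simulator: genealogies, SNP spectra, genotypes.

This is both the synthetic-data generator and the Monte-Carlo engine
behind the composite likelihood: the same per-SNP genealogy process
produces (a) observed-style datasets (one sampled infinite-sites
mutation per genealogy) and (b) expected joint-SFS estimates
(branch-length-weighted accumulation over genealogies, a lower-variance
estimator of the same conditional-on-polymorphism expectation).

Times are in generations, sizes in diploid individuals; 2Nm-scaled
migration is converted to raw per-lineage rates by the demography layer.
SNPs are simulated on independent genealogies (linkage equilibrium).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernel
from .demography import POPULATIONS, DemographicModel
from .genotypes import MISSING, GenotypeTable
from .sfs import FoldedJointSFS, all_pairs, fold_grid


def derive_seeds(seed: int, n: int, stream: str = "") -> np.ndarray:
    """Deterministic child seeds (< 2^31) from one root seed.

    ``stream`` namespaces substreams so that independent stages fed the
    same root seed do not share randomness.
    """
    key = [seed] + [ord(c) for c in stream]
    ss = np.random.SeedSequence(key)
    return (ss.generate_state(n, dtype=np.uint64) % (2 ** 31 - 1)).astype(np.int64)


@dataclass
class Demography:
    """Low-level piecewise demography the kernels consume.

    ``sizes``: present diploid size per deme; ``migration``: raw backward
    per-generation lineage rates (entry (i, j): deme i -> j);
    ``events``: time-ordered merges (time, src, dst, new dest size).
    """

    sizes: np.ndarray
    migration: np.ndarray
    events: list[tuple[float, int, int, float]]
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        self.migration = np.asarray(self.migration, dtype=float)
        nd = self.sizes.size
        if self.migration.shape != (nd, nd):
            raise ValueError("migration matrix shape does not match demes")
        times = [e[0] for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("merge events must be strictly time-ordered")
        if self.labels is None:
            self.labels = tuple(f"pop{i}" for i in range(nd))

    @classmethod
    def from_model(cls, model: DemographicModel) -> "Demography":
        return cls(model.present_sizes(), model.migration_matrix(),
                   model.merge_events(), POPULATIONS)

    def _kernel_args(self) -> tuple:
        ev = self.events
        return (self.sizes,
                self.migration,
                np.array([e[0] for e in ev], dtype=float),
                np.array([e[1] for e in ev], dtype=np.int64),
                np.array([e[2] for e in ev], dtype=np.int64),
                np.array([e[3] for e in ev], dtype=float))


def _as_demography(model) -> Demography:
    if isinstance(model, Demography):
        return model
    if isinstance(model, DemographicModel):
        return Demography.from_model(model)
    raise TypeError(f"expected DemographicModel or Demography, got {type(model)}")


def _sample_sizes_array(demog: Demography, sample_sizes) -> np.ndarray:
    """Haplotype sample sizes per deme, from an array or a {label: n} dict."""
    if isinstance(sample_sizes, dict):
        arr = np.array([sample_sizes.get(lbl, 0) for lbl in demog.labels], dtype=np.int64)
    else:
        arr = np.asarray(sample_sizes, dtype=np.int64)
    if arr.size != demog.sizes.size:
        raise ValueError("sample sizes do not match demes")
    if (arr < 0).any() or arr.sum() < 2:
        raise ValueError("need at least 2 sampled haplotypes in total")
    return arr


# ---------------------------------------------------------------------------
# genealogies
# ---------------------------------------------------------------------------

@dataclass
class Genealogy:
    """A single simulated binary genealogy (times in generations)."""

    birth_times: np.ndarray     # node creation times (tips at 0)
    branch_lengths: np.ndarray  # branch above each node (root: 0)
    parents: np.ndarray         # parent node index (-1 for root)
    configs: np.ndarray         # per-node descendant counts per deme
    tmrca: float

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths.sum())


def simulate_genealogy(model, sample_sizes, seed: int) -> Genealogy:
    """Simulate one structured-coalescent genealogy under the model."""
    demog = _as_demography(model)
    ss = _sample_sizes_array(demog, sample_sizes)
    n_nodes, rt, birth, blen, parent, cfg = _kernel.sim_single_tree(
        ss, *demog._kernel_args(), int(seed))
    return Genealogy(birth, blen, parent, cfg, float(rt))


def genealogy_stats(model, sample_sizes, n_reps: int, seed: int):
    """Vectorised per-replicate (TMRCA, total length) plus branch arrays.

    Returns (root_times, total_lengths, branch_lengths, branch_counts,
    offsets); branches of replicate r live in slice offsets[r]:offsets[r+1].
    """
    demog = _as_demography(model)
    ss = _sample_sizes_array(demog, sample_sizes)
    return _kernel.sim_tree_stats(int(n_reps), ss, *demog._kernel_args(), int(seed))


# ---------------------------------------------------------------------------
# SNP spectra
# ---------------------------------------------------------------------------

def simulate_snp_configs(model, sample_sizes, n_snps: int, seed: int,
                         with_masks: bool = False, n_trees: int | None = None):
    """Per-SNP derived-allele count configurations (one mutation per SNP).

    ``n_trees`` independent genealogies (default: one per SNP) are
    simulated and each SNP's mutation is drawn from the pooled branches
    with probability proportional to branch length. Pooling implements
    the infinite-sites conditioning on polymorphism — a genealogy
    carries a segregating site with probability proportional to its
    total length — so every SNP is polymorphic in the pooled sample and
    the per-SNP configuration distribution matches the branch-length
    expectation E[l_config] / E[L]. With ``with_masks`` the carrier
    bitmask per SNP is returned too (total sample must fit 64 haplotypes).
    """
    demog = _as_demography(model)
    ss = _sample_sizes_array(demog, sample_sizes)
    ntot = int(ss.sum())
    if with_masks and ntot > 64:
        raise ValueError("carrier bitmasks support at most 64 haplotypes")
    kseed, mseed = derive_seeds(seed, 2, "snp-configs")
    pool_len, pool_cfg, pool_msk, n_br = _kernel.sim_branch_pool(
        int(n_trees or n_snps), ss, *demog._kernel_args(), int(kseed), with_masks)
    pool_len = pool_len[:n_br]
    rng = np.random.default_rng(int(mseed))
    idx = rng.choice(n_br, size=int(n_snps), p=pool_len / pool_len.sum())
    configs = pool_cfg[idx]
    masks = pool_msk[idx]
    return (configs, masks) if with_masks else configs


def configs_to_pairwise_sfs(configs: np.ndarray, labels, sample_sizes) -> dict:
    """Fold per-SNP configurations into all pairwise joint spectra."""
    labels = tuple(labels)
    ss = np.asarray(sample_sizes, dtype=np.int64)
    out: dict[tuple[str, str], FoldedJointSFS] = {}
    for a, b in all_pairs(list(labels)):
        ia, ib = labels.index(a), labels.index(b)
        grid = np.zeros((ss[ia] + 1, ss[ib] + 1))
        np.add.at(grid, (configs[:, ia], configs[:, ib]), 1.0)
        out[(a, b)] = FoldedJointSFS(a, b, int(ss[ia]), int(ss[ib]), fold_grid(grid))
    return out


def simulate_sfs(model, sample_sizes, n_snps: int, seed: int) -> dict:
    """All pairwise folded joint SFS from per-SNP mutation sampling.

    Returns {(popA, popB): FoldedJointSFS} over the canonical pair order.
    Deterministic for a fixed seed.
    """
    demog = _as_demography(model)
    ss = _sample_sizes_array(demog, sample_sizes)
    configs = simulate_snp_configs(demog, ss, n_snps, seed)
    return configs_to_pairwise_sfs(configs, demog.labels, ss)


def expected_joint_weights(model, sample_sizes, n_sims: int, seed: int) -> np.ndarray:
    """Branch-length-weighted joint configuration weights (unnormalised).

    Shape: (n_0+1, ..., n_{d-1}+1). Normalising over polymorphic entries
    estimates the expected joint SFS conditional on polymorphism.
    """
    demog = _as_demography(model)
    ss = _sample_sizes_array(demog, sample_sizes)
    w = _kernel.sim_expected_weights(int(n_sims), ss, *demog._kernel_args(), int(seed))
    return w.reshape(tuple(ss + 1))


def expected_pairwise_folded_weights(model, sample_sizes, n_sims: int, seed: int,
                                     pairs_idx: list[tuple[int, int]]) -> list[np.ndarray]:
    """Folded pairwise branch-length weights, accumulated in the kernel.

    Equivalent to marginalising :func:`expected_joint_weights` to each
    deme pair and folding, but without materialising the joint array —
    this is the fast path behind the inference loop. Returns one
    (n_a+1)x(n_b+1) folded weight grid per pair.
    """
    demog = _as_demography(model)
    ss = _sample_sizes_array(demog, sample_sizes)
    pair_a, pair_b, fold_flat, fold_off, nb_plus1 = _pair_fold_tables(
        tuple(ss.tolist()), tuple(pairs_idx))
    out = _kernel.sim_expected_pair_folded(
        int(n_sims), ss, *demog._kernel_args(), int(seed),
        pair_a, pair_b, fold_flat, fold_off, nb_plus1)
    return [out[fold_off[k]:fold_off[k + 1]].reshape(ss[ia] + 1, ss[ib] + 1)
            for k, (ia, ib) in enumerate(pairs_idx)]


_PAIR_FOLD_CACHE: dict = {}


def _pair_fold_tables(sizes: tuple, pairs_idx: tuple):
    """Cached flattened fold-lookup tables for a (sizes, pairs) combination."""
    key = (sizes, pairs_idx)
    if key not in _PAIR_FOLD_CACHE:
        from .sfs import _fold_indices

        pair_a = np.array([p[0] for p in pairs_idx], dtype=np.int64)
        pair_b = np.array([p[1] for p in pairs_idx], dtype=np.int64)
        fold_parts = []
        nb_plus1 = np.zeros(len(pairs_idx), dtype=np.int64)
        for k, (ia, ib) in enumerate(pairs_idx):
            fi, fj = _fold_indices(int(sizes[ia]), int(sizes[ib]))
            nb_plus1[k] = sizes[ib] + 1
            fold_parts.append((fi * (sizes[ib] + 1) + fj).ravel().astype(np.int64))
        fold_off = np.zeros(len(pairs_idx) + 1, dtype=np.int64)
        np.cumsum([p.size for p in fold_parts], out=fold_off[1:])
        _PAIR_FOLD_CACHE[key] = (pair_a, pair_b, np.concatenate(fold_parts),
                                 fold_off, nb_plus1)
    return _PAIR_FOLD_CACHE[key]


# ---------------------------------------------------------------------------
# genotype tables (GBS-style synthetic data)
# ---------------------------------------------------------------------------

def simulate_genotypes_with_missingness(
    model,
    sample_sizes_diploid,
    n_loci: int,
    snps_per_locus: int = 1,
    missing_rate: float = 0.0,
    seed: int = 0,
    locality_size: int = 4,
) -> GenotypeTable:
    """GBS-style diploid genotype table with heterogeneous loci and missing data.

    Haplotypes are paired into diploids within each population; SNPs are
    grouped into ``n_loci`` loci of ``snps_per_locus`` SNPs (each SNP on
    its own genealogy — loci are grouping labels, not linkage blocks);
    every genotype is masked independently with probability
    ``missing_rate``. Localities split each population's individuals
    into consecutive chunks of ``locality_size``.
    """
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must lie in [0, 1]")
    demog = _as_demography(model)
    if isinstance(sample_sizes_diploid, dict):
        dips = np.array([sample_sizes_diploid.get(l, 0) for l in demog.labels],
                        dtype=np.int64)
    else:
        dips = np.asarray(sample_sizes_diploid, dtype=np.int64)
    haps = 2 * dips
    ntot = int(haps.sum())
    if ntot > 64:
        raise ValueError("genotype simulation supports at most 64 haplotypes in total")
    n_snps = n_loci * snps_per_locus
    kseed, mseed = derive_seeds(seed, 2, "genotypes")
    configs, masks = simulate_snp_configs(demog, haps, n_snps, int(kseed),
                                          with_masks=True)

    hap_matrix = (
        (masks[None, :] >> np.arange(ntot, dtype=np.uint64)[:, None])
        & np.uint64(1)).astype(np.int8)
    genotypes = hap_matrix[0::2] + hap_matrix[1::2]  # (n_individuals, n_snps)

    rng = np.random.default_rng(int(mseed))
    if missing_rate > 0:
        drop = rng.random(genotypes.shape) < missing_rate
        genotypes = np.where(drop, np.int8(MISSING), genotypes)

    individual_ids: list[str] = []
    locality_ids: list[str] = []
    population_ids: list[str] = []
    for d, lbl in enumerate(demog.labels):
        for i in range(int(dips[d])):
            individual_ids.append(f"{lbl}_ind{i:03d}")
            locality_ids.append(f"{lbl}_loc{i // locality_size}")
            population_ids.append(lbl)

    sites = pd.DataFrame({
        "locus_id": [f"locus_{s // snps_per_locus:06d}" for s in range(n_snps)],
        "pos": [s % snps_per_locus for s in range(n_snps)],
    })
    return GenotypeTable(genotypes, individual_ids, locality_ids, sites,
                         population_ids)


# ---------------------------------------------------------------------------
# finite-sites sequence mode (for closed-form diversity checks)
# ---------------------------------------------------------------------------

def simulate_locus_pi(model, sample_sizes, n_loci: int, locus_length: int,
                      mu: float, seed: int) -> np.ndarray:
    """Per-locus nucleotide diversity under a finite-sites mutation model.

    Each locus is one genealogy; each branch receives
    Poisson(mu * L * length) mutations; a mutation on a branch with x
    descendant copies contributes x (n - x) pairwise differences. The
    returned per-locus pi (per site) has expectation 4 N mu for a single
    constant-size population.
    """
    demog = _as_demography(model)
    ss = _sample_sizes_array(demog, sample_sizes)
    n = int(ss.sum())
    kseed, pseed = derive_seeds(seed, 2, "seq")
    _, _, br_len, br_cnt, offsets = _kernel.sim_tree_stats(
        int(n_loci), ss, *demog._kernel_args(), int(kseed))
    rng = np.random.default_rng(int(pseed))
    muts = rng.poisson(mu * locus_length * br_len)
    pair_diffs = muts * br_cnt * (n - br_cnt)
    n_pairs = n * (n - 1) / 2
    out = np.zeros(int(n_loci))
    sums = np.add.reduceat(pair_diffs, offsets[:-1])
    sums[offsets[:-1] == offsets[1:]] = 0.0
    out[:] = sums / (n_pairs * locus_length)
    return out
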