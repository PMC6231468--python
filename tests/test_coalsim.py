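"""Structured-coalescent simulator: closed forms, oracle cross-check, plumbing."""

import numpy as np
import pytest

import msprime

from demosfs.coalsim import (Demography, derive_seeds, genealogy_stats,
                             simulate_genealogy, simulate_genotypes_with_missingness,
                             simulate_locus_pi, simulate_sfs, simulate_snp_configs)
from demosfs.demography import MODEL3_POINT_ESTIMATES, POPULATIONS, build_model
from demosfs.genotypes import MISSING
from demosfs.inference import estimate_expected_sfs
from demosfs.sfs import fold_grid, folded_mask


def single_pop(n=10_000.0):
    return Demography(np.array([n]), np.zeros((1, 1)), [], ("A",))


def isolation_pair(n=10_000.0, t=20_000.0, n_anc=15_000.0):
    return Demography(np.array([n, n]), np.zeros((2, 2)),
                      [(t, 1, 0, n_anc)], ("A", "B"))


class TestClosedForms:
    def test_tmrca_two_lineages(self):
        """E[TMRCA] = 2N generations for n=2 in one constant deme."""
        n = 10_000.0
        root_t, total_len, *_ = genealogy_stats(single_pop(n), [2], 4000, seed=5)
        se = root_t.std(ddof=1) / np.sqrt(root_t.size)
        assert abs(root_t.mean() - 2 * n) < 3 * se
        # total branch length for n=2 is twice the TMRCA: mean 4N
        se_l = total_len.std(ddof=1) / np.sqrt(total_len.size)
        assert abs(total_len.mean() - 4 * n) < 3 * se_l

    def test_split_with_no_migration_bounds_coalescence(self):
        """One lineage per deme cannot coalesce before the merge time."""
        t = 20_000.0
        root_t, *_ = genealogy_stats(isolation_pair(t=t), [1, 1], 500, seed=9)
        assert (root_t > t).all()

    def test_folded_sfs_single_pop_n4(self):
        """Neutral folded SFS for n=4.

        The unfolded spectrum is proportional to 1/i, so folding pools
        (1 + 1/3, 1/2), which normalises to (8/11, 3/11) over minor
        counts (1, 2)."""
        configs = simulate_snp_configs(single_pop(), [4], 40_000, seed=3)
        k = np.minimum(configs[:, 0], 4 - configs[:, 0])
        counts = np.bincount(k, minlength=3)[1:]
        freq = counts / counts.sum()
        expect = 8 / 11
        # binomial 3-SE tolerance at 40k SNPs (pooled branch sampling is
        # slightly dependent across SNPs; allow a small extra margin)
        assert abs(freq[0] - expect) < 4 * np.sqrt(expect * (1 - expect) / 40_000)


class TestMsprimeOracle:
    def _msprime_demography(self, model):
        demog = msprime.Demography()
        sizes = model.present_sizes()
        for lbl, n in zip(POPULATIONS, sizes):
            demog.add_population(name=lbl, initial_size=n)
        mig = model.migration_matrix()
        for i in range(4):
            for j in range(4):
                if mig[i, j] > 0:
                    # msprime matrix entry (i, j): backward lineage rate i -> j
                    demog.migration_matrix[i, j] = mig[i, j]
        alive = mig.copy()
        for t, src, dst, size in model.merge_events():
            demog.add_mass_migration(time=t, source=POPULATIONS[src],
                                     dest=POPULATIONS[dst], proportion=1.0)
            demog.add_population_parameters_change(
                time=t, population=POPULATIONS[dst], initial_size=size)
            for d in (src, dst):
                for j in range(4):
                    for a, b in ((d, j), (j, d)):
                        if alive[a, b] > 0:
                            demog.add_migration_rate_change(
                                time=t, source=POPULATIONS[a],
                                dest=POPULATIONS[b], rate=0.0)
                            alive[a, b] = 0.0
        demog.sort_events()
        return demog

    def test_expected_pair_sfs_matches_msprime(self):
        """Folded joint SFS under the best-fit 4-population history agrees
        with an independent coalescent implementation (branch-mode AFS)."""
        model = build_model(3, MODEL3_POINT_ESTIMATES)
        n_dip = 2  # 4 haplotypes per population
        demog = self._msprime_demography(model)
        reps = msprime.sim_ancestry(
            samples={lbl: n_dip for lbl in POPULATIONS}, demography=demog,
            num_replicates=4000, random_seed=1234)
        acc = {}
        pairs = [("WAS", "EGB"), ("PW", "WGB"), ("EGB", "PW")]
        for ts in reps:
            sets = {lbl: ts.samples(population=k)
                    for k, lbl in enumerate(POPULATIONS)}
            for a, b in pairs:
                afs = ts.allele_frequency_spectrum(
                    sample_sets=[sets[a], sets[b]], mode="branch",
                    polarised=True, span_normalise=False)
                acc[(a, b)] = acc.get((a, b), 0.0) + afs
        ours = estimate_expected_sfs(model, {l: 2 * n_dip for l in POPULATIONS},
                                     n_sims=40_000, seed=77, pairs=pairs)
        for pair in pairs:
            folded = fold_grid(acc[pair])
            mask = folded_mask(2 * n_dip, 2 * n_dip)
            ref = np.where(mask, 0.0, folded)
            ref /= ref.sum()
            tv = 0.5 * np.abs(ref - np.where(mask, 0.0, ours[pair])).sum()
            assert tv < 0.03, f"TV distance {tv:.4f} for pair {pair}"


class TestDeterminismAndPlumbing:
    def test_same_seed_identical_sfs(self):
        model = build_model(3, MODEL3_POINT_ESTIMATES)
        a = simulate_sfs(model, [4, 4, 4, 4], 200, seed=11)
        b = simulate_sfs(model, [4, 4, 4, 4], 200, seed=11)
        for pair in a:
            np.testing.assert_array_equal(a[pair].counts, b[pair].counts)

    def test_derived_seeds_are_stable_and_stream_separated(self):
        a = derive_seeds(42, 3, "x")
        b = derive_seeds(42, 3, "x")
        c = derive_seeds(42, 3, "y")
        np.testing.assert_array_equal(a, b)
        assert (a != c).any()
        assert (a >= 0).all() and (a < 2 ** 31).all()

    def test_genealogy_structure(self):
        g = simulate_genealogy(single_pop(), [6], seed=2)
        n_nodes = g.parents.size
        assert n_nodes == 2 * 6 - 1
        assert (g.parents[:-1] > np.arange(n_nodes - 1)).all()
        assert g.parents[-1] == -1
        assert g.tmrca == pytest.approx(g.birth_times.max())

    @pytest.mark.parametrize("rate", [0.0, 0.3, 1.0])
    def test_missingness_rate(self, rate):
        model = build_model(3, MODEL3_POINT_ESTIMATES)
        table = simulate_genotypes_with_missingness(
            model, [4, 4, 4, 4], n_loci=150, snps_per_locus=2,
            missing_rate=rate, seed=6)
        frac = (table.genotypes == MISSING).mean()
        n = table.genotypes.size
        assert abs(frac - rate) <= 3 * np.sqrt(rate * (1 - rate) / n) + 1e-12

    def test_genotype_table_layout(self):
        model = build_model(3, MODEL3_POINT_ESTIMATES)
        table = simulate_genotypes_with_missingness(
            model, [4, 4, 4, 4], n_loci=50, snps_per_locus=3,
            missing_rate=0.1, seed=6, locality_size=2)
        assert table.n_individuals == 16
        assert table.n_sites == 150
        assert table.sites["locus_id"].nunique() == 50
        assert table.population_ids.count("WAS") == 4
        # two localities of two individuals per population
        assert len(set(table.locality_ids)) == 8

    def test_locus_pi_expectation_single_pop(self):
        """E[pi] = 4 N mu under a finite-sites single population."""
        n, mu, L = 5_000.0, 1e-8, 2_000
        pi = simulate_locus_pi(single_pop(n), [2], 4_000, L, mu, seed=13)
        se = pi.std(ddof=1) / np.sqrt(pi.size)
        assert abs(pi.mean() - 4 * n * mu) < 3 * se
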