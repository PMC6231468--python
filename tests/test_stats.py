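"""Diversity statistics, F_ST variance components, and PCA."""

import numpy as np
import pytest

from demosfs.genotypes import MISSING
from demosfs.stats import (expected_heterozygosity, inbreeding_coefficient,
                           locality_diversity, nucleotide_diversity, pairwise_fst,
                           pca_scores, subsampled_stats)

from conftest import make_table, random_table


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation's algebra)
# ---------------------------------------------------------------------------

def pi_by_pair_enumeration(alt, n):
    """Mean pairwise difference at a site by counting differing pairs."""
    ref = n - alt
    return alt * ref / (n * (n - 1) / 2)


def fst_anova_oracle(alt_a, n_a, alt_b, n_b):
    """One-way ANOVA on 0/1 allele indicators, explicit sums of squares."""
    sig_a = sig_t = 0.0
    for ka, na, kb, nb in zip(alt_a, n_a, alt_b, n_b):
        y = np.concatenate([np.repeat([1.0, 0.0], [ka, na - ka]),
                            np.repeat([1.0, 0.0], [kb, nb - kb])])
        groups = np.repeat([0, 1], [na, nb])
        gm = y.mean()
        means = [y[groups == g].mean() for g in (0, 1)]
        ss_among = sum(n * (m - gm) ** 2 for n, m in zip((na, nb), means))
        ss_within = sum(((y[groups == g] - means[g]) ** 2).sum() for g in (0, 1))
        n_tot = na + nb
        msp = ss_among / 1
        msg = ss_within / (n_tot - 2)
        n_c = (n_tot - (na ** 2 + nb ** 2) / n_tot) / 1
        s2a = (msp - msg) / n_c
        sig_a += s2a
        sig_t += s2a + msg
    return sig_a / sig_t


class TestSiteStatistics:
    def test_he_examples(self):
        assert expected_heterozygosity([0.5, 0.5]) == pytest.approx(0.5)
        assert expected_heterozygosity([1.0, 0.0]) == 0.0
        assert expected_heterozygosity([0.25, 0.75]) == pytest.approx(0.375)

    def test_pi_examples(self):
        """4 haplotypes split 2/2 -> 2/3 (= 4 differing pairs / 6 pairs);
        a heterozygous single pair -> 1; monomorphic -> 0."""
        assert nucleotide_diversity([2], [4]) == pytest.approx(2 / 3)
        assert nucleotide_diversity([1], [2]) == pytest.approx(1.0)
        assert nucleotide_diversity([0], [4]) == 0.0

    def test_fis_examples(self):
        assert inbreeding_coefficient([0.5], [0.5]) == pytest.approx(0.0)
        assert inbreeding_coefficient([0.0], [0.5]) == pytest.approx(1.0)
        assert inbreeding_coefficient([0.3], [0.5]) == pytest.approx(0.4)
        assert np.isnan(inbreeding_coefficient([0.0], [0.0]))

    def test_pi_matches_pair_enumeration(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 20)) * 2
            alt = int(rng.integers(0, n + 1))
            assert nucleotide_diversity([alt], [n]) == pytest.approx(
                pi_by_pair_enumeration(alt, n))

    def test_he_pi_allele_label_swap_invariance(self, rng):
        for _ in range(20):
            n = 12
            alt = int(rng.integers(0, n + 1))
            assert nucleotide_diversity([alt], [n]) == pytest.approx(
                nucleotide_diversity([n - alt], [n]))
            p = alt / n
            assert expected_heterozygosity([p, 1 - p]) == pytest.approx(
                expected_heterozygosity([1 - p, p]))


class TestFst:
    def test_fixed_differences_give_one(self):
        table = make_table([[0, 0], [0, 0], [2, 2], [2, 2]])
        fst = pairwise_fst(table, np.array([0, 1]), np.array([2, 3]))
        assert fst == pytest.approx(1.0)

    def test_toy_variance_components_hand_case(self):
        """2 pops x 2 diploids, one site at frequencies 0.75 vs 0.25."""
        table = make_table([[2, ], [1, ], [1, ], [0, ]])
        fst = pairwise_fst(table, np.array([0, 1]), np.array([2, 3]))
        assert fst == pytest.approx(fst_anova_oracle([3], [4], [1], [4]))

    def test_matches_anova_oracle_on_random_tables(self, rng):
        for _ in range(40):
            table = random_table(rng, n_ind=8, n_sites=6, missing_rate=0.2)
            ga, gb = np.arange(4), np.arange(4, 8)
            fst = pairwise_fst(table, ga, gb)
            alt_a, n_a = table.allele_counts(ga)
            alt_b, n_b = table.allele_counts(gb)
            ok = (n_a >= 2) & (n_b >= 2)
            tot = alt_a + alt_b
            poly = ok & (tot > 0) & (tot < n_a + n_b)
            if not poly.any():
                assert np.isnan(fst)
                continue
            oracle = fst_anova_oracle(alt_a[poly], n_a[poly],
                                      alt_b[poly], n_b[poly])
            assert fst == pytest.approx(oracle)

    def test_too_few_individuals_rejected(self):
        table = make_table([[0], [1], [2]])
        with pytest.raises(ValueError):
            pairwise_fst(table, np.array([0]), np.array([1, 2]))


class TestPca:
    def test_duplicated_individual_identical_scores(self, rng):
        table = random_table(rng, n_ind=6, n_sites=20, missing_rate=0.0)
        g = np.vstack([table.genotypes, table.genotypes[0]])
        dup = make_table(g)
        scores, _ = pca_scores(dup, 2)
        np.testing.assert_allclose(scores[0], scores[-1], atol=1e-8)

    def test_explained_variance_fractions(self, rng):
        table = random_table(rng, n_ind=10, n_sites=30, missing_rate=0.1)
        _, frac = pca_scores(table, 5)
        assert frac.sum() <= 1.0 + 1e-9
        assert (np.diff(frac) <= 1e-12).all()

    def test_mean_imputation_keeps_missing_neutral(self):
        """An individual missing a site scores as if at the site mean."""
        g = np.array([[0, 0], [2, 2], [1, MISSING]], dtype=np.int8)
        scores, _ = pca_scores(make_table(g), 1)
        # ind2 sits exactly between the two homozygote individuals on PC1
        assert scores[2, 0] == pytest.approx((scores[0, 0] + scores[1, 0]) / 2,
                                             abs=1e-8)

    def test_all_monomorphic_is_fatal(self):
        with pytest.raises(ValueError):
            pca_scores(make_table([[1, 1], [1, 1]]), 1)


class TestLocalityDiversity:
    def test_against_direct_formulas(self):
        g = [[0, 1], [1, 1]]
        stats = locality_diversity(make_table(g))[0]
        # site freqs p = 1/4 and 2/4 over 4 haplotypes
        he = np.mean([2 * 0.25 * 0.75, 2 * 0.5 * 0.5])
        pi = np.mean([pi_by_pair_enumeration(1, 4), pi_by_pair_enumeration(2, 4)])
        ho = np.mean([0.5, 1.0])
        assert stats.h_exp == pytest.approx(he)
        assert stats.pi == pytest.approx(pi)
        assert stats.f_is == pytest.approx(np.mean(
            [1 - 0.5 / (2 * 0.25 * 0.75), 1 - 1.0 / 0.5]))

    def test_subsampling_fixed_point(self, rng):
        """A locality with exactly n_per_locality individuals yields 20
        identical replicates equal to the full-sample statistics."""
        table = random_table(rng, n_ind=4, n_sites=15, missing_rate=0.1)
        full = locality_diversity(table)[0]
        sub = subsampled_stats(table, n_per_locality=4, replicates=20, seed=1)[0]
        assert len(sub.replicates) == 20
        assert sub.replicates["h_exp"].nunique() == 1
        assert sub.h_exp == pytest.approx(full.h_exp)
        assert sub.pi == pytest.approx(full.pi)
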