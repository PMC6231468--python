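"""Composite likelihood, ECM machinery, AIC selection, percentile intervals."""

import numpy as np
import pandas as pd
import pytest

from demosfs.coalsim import Demography, simulate_sfs
from demosfs.demography import MODEL3_POINT_ESTIMATES, PARAM_NAMES, build_model
from demosfs.inference import (DEFAULT_SEARCH_RANGES, FitResult, InferenceError,
                               _draw_initial_params, aic_select,
                               composite_log_likelihood, ecm_fit,
                               estimate_expected_sfs, multi_run_fit,
                               percentile_interval)
from demosfs.sfs import FoldedJointSFS, folded_mask

SIZES = dict(zip(("WAS", "EGB", "PW", "WGB"), [8, 8, 8, 8]))


def toy_observed(counts_by_entry, n=4):
    """One-pair observed SFS with counts placed on unmasked entries."""
    counts = np.zeros((n + 1, n + 1))
    for (i, j), m in counts_by_entry.items():
        counts[i, j] = m
    return {("A", "B"): FoldedJointSFS("A", "B", n, n, counts)}


def probs_like(observed, values_by_entry):
    sfs = observed[("A", "B")]
    p = np.zeros_like(sfs.counts)
    for (i, j), v in values_by_entry.items():
        p[i, j] = v
    return {("A", "B"): p}


class TestCompositeLogLikelihood:
    def test_hand_example(self):
        """{10, 30} against {0.25, 0.75} -> 10 ln .25 + 30 ln .75 = -22.4930."""
        obs = toy_observed({(1, 0): 10, (1, 1): 30})
        p = probs_like(obs, {(1, 0): 0.25, (1, 1): 0.75})
        assert composite_log_likelihood(obs, p) == pytest.approx(
            10 * np.log(0.25) + 30 * np.log(0.75))
        assert composite_log_likelihood(obs, p) == pytest.approx(-22.4934, abs=5e-5)

    def test_degenerate_point_mass(self):
        obs = toy_observed({(1, 1): 17})
        p = probs_like(obs, {(1, 1): 1.0})
        assert composite_log_likelihood(obs, p) == 0.0

    def test_multinomial_mle_maximises(self, rng):
        """p = m / sum(m) beats every other probability vector (grid scan)."""
        obs = toy_observed({(1, 0): 12, (0, 1): 5, (1, 1): 23})
        m = np.array([12.0, 5.0, 23.0])
        best = composite_log_likelihood(obs, probs_like(
            obs, {(1, 0): m[0] / 40, (0, 1): m[1] / 40, (1, 1): m[2] / 40}))
        for _ in range(200):
            q = rng.dirichlet([1, 1, 1])
            ll = composite_log_likelihood(obs, probs_like(
                obs, {(1, 0): q[0], (0, 1): q[1], (1, 1): q[2]}))
            assert ll <= best + 1e-9

    def test_shape_mismatch_fatal(self):
        obs = toy_observed({(1, 0): 1})
        with pytest.raises(InferenceError):
            composite_log_likelihood(obs, {("A", "B"): np.ones((3, 3)) / 9})


class TestExpectedSfs:
    def test_probabilities_normalised_and_deterministic(self):
        model = build_model(3, MODEL3_POINT_ESTIMATES)
        p1 = estimate_expected_sfs(model, SIZES, 500, seed=3)
        p2 = estimate_expected_sfs(model, SIZES, 500, seed=3)
        assert len(p1) == 6
        for pair, p in p1.items():
            mask = folded_mask(*p.shape - np.array([1, 1]))
            assert p[~mask].sum() == pytest.approx(1.0)
            assert (p[~mask] > 0).all()
            np.testing.assert_array_equal(p, p2[pair])

    def test_monte_carlo_convergence(self):
        """Total-variation distance between a cheap and an expensive
        estimate of the same expected SFS is small."""
        model = build_model(3, MODEL3_POINT_ESTIMATES)
        lo = estimate_expected_sfs(model, SIZES, 10_000, seed=5)
        hi = estimate_expected_sfs(model, SIZES, 100_000, seed=6)
        for pair in lo:
            tv = 0.5 * np.abs(lo[pair] - hi[pair]).sum()
            assert tv < 0.02


class TestEcmFit:
    @pytest.fixture(scope="class")
    def observed(self):
        model = build_model(3, MODEL3_POINT_ESTIMATES)
        return simulate_sfs(model, [8, 8, 8, 8], 500, seed=21)

    def test_monotone_under_fixed_seed(self, observed):
        """Coordinate ascent never decreases lnCL when every evaluation
        shares one random-number stream: fitting with more cycles from
        the same seed can only improve the final value."""
        traj = []
        for nc in (1, 2, 3):
            _, ll_nc = ecm_fit(observed, 3, n_cycles=nc, n_sims=300, seed=9,
                               crn_mode="fixed", grid_points=4, refine_iters=1,
                               tol=0.0)
            traj.append(ll_nc)
        assert traj == sorted(traj)

    def test_zero_polymorphic_is_fatal(self):
        from demosfs.sfs import all_pairs
        empty = {pair: FoldedJointSFS(pair[0], pair[1], 4, 4, np.zeros((5, 5)))
                 for pair in all_pairs(["WAS", "EGB", "PW", "WGB"])}
        with pytest.raises(InferenceError, match="polymorphic"):
            ecm_fit(empty, 3)

    def test_inverted_search_range_fatal(self, observed):
        with pytest.raises(InferenceError, match="inverted"):
            ecm_fit(observed, 3, search_ranges={"N_WAS": (1e5, 1e3)})

    def test_initial_points_ordered_and_in_range(self, rng):
        for _ in range(100):
            p = _draw_initial_params(rng, DEFAULT_SEARCH_RANGES)
            assert p["T_1"] < p["T_2"] < p["T_3"]
            for k in PARAM_NAMES:
                lo, hi = DEFAULT_SEARCH_RANGES[k]
                assert lo * 0.9 <= p[k] <= hi * 1.1


class TestMultiRunAndSelection:
    @pytest.fixture(scope="class")
    def tiny_fit(self):
        model = build_model(3, MODEL3_POINT_ESTIMATES)
        observed = simulate_sfs(model, [8, 8, 8, 8], 400, seed=31)
        fit = multi_run_fit(observed, 3, n_runs=2, n_cycles=2, n_sims=300,
                            seed=5, grid_points=4, refine_iters=1,
                            final_n_sims=2000)
        return observed, fit

    def test_best_run_dominates_and_deterministic(self, tiny_fit):
        observed, fit = tiny_fit
        assert fit.ln_cl == fit.runs["ln_cl"].max()
        fit2 = multi_run_fit(observed, 3, n_runs=2, n_cycles=2, n_sims=300,
                             seed=5, grid_points=4, refine_iters=1,
                             final_n_sims=2000)
        assert fit2.ln_cl == fit.ln_cl
        assert fit2.params == fit.params

    def test_aic_formula_and_log10_view(self, tiny_fit):
        _, fit = tiny_fit
        assert fit.aic == pytest.approx(2 * 15 - 2 * fit.ln_cl)
        assert fit.log10_cl == pytest.approx(fit.ln_cl / np.log(10))

    def test_aic_selection_against_reported_values(self):
        """AIC ranking of the three fitted histories: the stepwise-chain
        model with deepest WAS divergence wins; at AIC gaps of several
        hundred units the relative likelihoods of the others vanish."""
        def fake_fit(mid, aic):
            return FitResult(model_id=mid, params={}, ln_cl=(2 * 15 - aic) / 2,
                             aic=aic, n_runs=1, runs=pd.DataFrame(),
                             sample_sizes={"WAS": 8}, n_snps=100.0)
        fits = [fake_fit(1, 149_266.0), fake_fit(2, 149_388.0),
                fake_fit(3, 148_750.0)]
        ranking = aic_select(fits)
        assert list(ranking["model_id"]) == [3, 1, 2]
        assert ranking["rel_likelihood"].iloc[0] == 1.0
        assert ranking["rel_likelihood"].iloc[1] == pytest.approx(0.0, abs=1e-50)

    def test_aic_trivial_formula(self):
        f = FitResult(model_id=1, params={}, ln_cl=-100.0, aic=2 * 2 - 2 * -100,
                      n_runs=1, runs=pd.DataFrame(), sample_sizes={}, n_snps=1.0)
        assert f.aic == 204

    def test_selection_requires_same_data(self):
        a = FitResult(1, {}, -10, 50, 1, pd.DataFrame(),
                      sample_sizes={"WAS": 8}, n_snps=100.0)
        b = FitResult(2, {}, -10, 50, 1, pd.DataFrame(),
                      sample_sizes={"WAS": 8}, n_snps=200.0)
        with pytest.raises(InferenceError):
            aic_select([a, b])

    def test_equal_aic_ties(self):
        a = FitResult(1, {}, -10, 50.0, 1, pd.DataFrame(), sample_sizes={},
                      n_snps=1.0)
        b = FitResult(2, {}, -10, 50.0, 1, pd.DataFrame(), sample_sizes={},
                      n_snps=1.0)
        r = aic_select([a, b])
        assert (r["rel_likelihood"] == 1.0).all()


class TestPercentiles:
    def test_hand_interval_1_to_100(self):
        """Replicates 1..100 -> 95% linear-interpolation interval
        [3.475, 97.525]."""
        lo, hi = percentile_interval(np.arange(1, 101))
        assert lo == pytest.approx(3.475)
        assert hi == pytest.approx(97.525)

    def test_degenerate_single_value(self):
        lo, hi = percentile_interval([5.0])
        assert lo == hi == 5.0
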