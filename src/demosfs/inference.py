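"""Composite-likelihood fitting of divergence/migration models to folded SFS.

The composite likelihood treats SNPs as independent multinomial draws
from the expected folded joint SFS (conditional on polymorphism), summed
over all included population pairs:

    lnCL = sum_pairs sum_entries m_e * ln p_e .

Expected spectra are estimated by structured-coalescent simulation, so
every likelihood evaluation is stochastic; optimisation therefore uses
expectation-conditional-maximisation (ECM) cycles — one bounded 1-D
line search per parameter in log space, with common random numbers
within a cycle so coordinate ascent is monotone despite Monte-Carlo
noise. Many independently initialised runs guard against local optima;
AIC compares fitted models; parametric bootstrap supplies percentile
confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .coalsim import (derive_seeds, expected_pairwise_folded_weights,
                      simulate_sfs)
from .demography import (MIGRATION_PARAMS, PARAM_NAMES, POPULATIONS, SIZE_PARAMS,
                         TIME_PARAMS, build_model)
from .sfs import FoldedJointSFS, all_pairs, folded_mask

logger = logging.getLogger(__name__)

N_ESTIMATED_PARAMS = len(PARAM_NAMES)  # 15; N_ANC is fixed, never estimated

DEFAULT_SEARCH_RANGES: dict[str, tuple[float, float]] = {
    **{k: (1e2, 1e6) for k in SIZE_PARAMS},
    **{k: (1e2, 1e5) for k in TIME_PARAMS},
    **{k: (1e-3, 1e2) for k in MIGRATION_PARAMS},
}


class InferenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# likelihood pieces
# ---------------------------------------------------------------------------

def composite_log_likelihood(observed: dict, expected_probs: dict) -> float:
    """lnCL = sum over pairs and unmasked entries of m * ln p.

    ``observed`` maps pair -> FoldedJointSFS, ``expected_probs`` maps the
    same pairs -> probability grids normalised over unmasked entries.
    """
    ll = 0.0
    for pair, sfs in observed.items():
        p = expected_probs[pair]
        if p.shape != sfs.counts.shape:
            raise InferenceError(f"shape mismatch for pair {pair}")
        sel = (~sfs.mask) & (sfs.counts > 0)  # m = 0 contributes nothing
        m = sfs.counts[sel]
        ll += float((m * np.log(p[sel])).sum())
    return ll


def estimate_expected_sfs(model, sample_sizes, n_sims: int, seed: int,
                          pairs: list[tuple[str, str]] | None = None) -> dict:
    """Simulated expected folded joint SFS probabilities for each pair.

    Joint configuration weights from ``n_sims`` genealogies are
    marginalised to every population pair, folded, masked at the
    monomorphic corner, floored at p_min = 0.1 / n_sims on unmasked
    zero-mass entries, and renormalised. Deterministic per seed.
    """
    if n_sims < 1:
        raise InferenceError("n_sims must be positive")
    if isinstance(sample_sizes, dict):
        labels = list(sample_sizes.keys())
        ss = np.array([sample_sizes[l] for l in labels], dtype=np.int64)
    else:
        labels = list(POPULATIONS)
        ss = np.asarray(sample_sizes, dtype=np.int64)
    if pairs is None:
        pairs = all_pairs(labels)
    pairs_idx = [(labels.index(a), labels.index(b)) for a, b in pairs]
    grids = expected_pairwise_folded_weights(model, ss, n_sims, seed, pairs_idx)
    floor = 0.1 / n_sims
    out: dict[tuple[str, str], np.ndarray] = {}
    for (a, b), (ia, ib), folded in zip(pairs, pairs_idx, grids):
        mask = folded_mask(int(ss[ia]), int(ss[ib]))
        p = np.where(mask, 0.0, folded)
        tot = p.sum()
        if tot <= 0:
            raise InferenceError(f"no polymorphic mass simulated for pair ({a},{b})")
        p = p / tot
        zero = (~mask) & (p <= 0)
        p[zero] = floor
        p[~mask] /= p[~mask].sum()
        out[(a, b)] = p
    return out


def _sizes_from_observed(observed: dict) -> dict[str, int]:
    """Per-population haplotype sample sizes implied by the observed spectra."""
    sizes: dict[str, int] = {}
    for (a, b), sfs in observed.items():
        for pop, n in ((a, sfs.n_a), (b, sfs.n_b)):
            if sizes.setdefault(pop, n) != n:
                raise InferenceError(f"inconsistent sample size for {pop}")
    return sizes


def _observed_snp_total(observed: dict) -> float:
    """Total SNP mass including the masked monomorphic corner (one pair)."""
    first = next(iter(observed.values()))
    return float(first.counts.sum())


# ---------------------------------------------------------------------------
# ECM optimisation
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    model_id: int
    params: dict[str, float]
    ln_cl: float
    aic: float
    n_runs: int
    runs: pd.DataFrame                       # one row per run: lnCL + parameters
    bootstrap_ci: dict[str, tuple[float, float]] | None = None
    sample_sizes: dict[str, int] = field(default_factory=dict)
    n_snps: float = 0.0

    @property
    def log10_cl(self) -> float:
        """lnCL re-expressed in log10 units."""
        return self.ln_cl / np.log(10.0)

    def to_frame(self) -> pd.DataFrame:
        rows = {"ln_cl": self.ln_cl, "aic": self.aic, **self.params}
        return pd.DataFrame([rows])


def _draw_initial_params(
    rng: np.random.Generator,
    ranges: dict[str, tuple[float, float]],
    t1_stratum: tuple[int, int] | None = None,
) -> dict[str, float]:
    """Log-uniform initial point with sequentially conditioned merge times.

    T_1 is drawn log-uniform over its full range (optionally within
    stratum r of s equal log-width strata, for stratified multistart),
    then T_2 log-uniform above T_1 and T_3 above T_2. Sorting three
    independent draws instead would concentrate T_1 near the range
    floor (the minimum of three uniforms), starving the multistart of
    deep-first-merge initial points.
    """
    params = {}
    for k in PARAM_NAMES:
        lo, hi = ranges[k]
        if k in MIGRATION_PARAMS:
            # start runs at moderate gene flow: an extreme initial 2Nm
            # (far tails of the search range) makes the first cycle's
            # merge-time searches collapse toward degenerate histories;
            # the search itself still covers the full range
            lo, hi = max(lo, 0.1), min(hi, 10.0)
        params[k] = 10 ** rng.uniform(np.log10(lo), np.log10(hi))
    lo1, hi1 = np.log10(ranges["T_1"][0]), np.log10(ranges["T_1"][1])
    if t1_stratum is not None:
        r, s = t1_stratum
        width = (hi1 - lo1) / s
        lo1, hi1 = lo1 + r * width, lo1 + (r + 1) * width
    hi2 = np.log10(ranges["T_2"][1])
    hi3 = np.log10(ranges["T_3"][1])
    t1 = rng.uniform(lo1, hi1)
    t2 = rng.uniform(t1 + 0.005, max(hi2, t1 + 0.01))
    t3 = rng.uniform(t2 + 0.005, max(hi3, t2 + 0.01))
    params["T_1"], params["T_2"], params["T_3"] = 10 ** t1, 10 ** t2, 10 ** t3
    return params


def _line_search(obj, lo_log: float, hi_log: float, x0_log: float, f0: float,
                 grid_points: int, refine_iters: int) -> tuple[float, float]:
    """Maximise -obj over [lo, hi] in log10 space: coarse grid, then Brent.

    The slice of a composite-likelihood surface along one parameter is
    often multimodal (compensatory ridges), so a global coarse scan
    precedes local refinement. The current point (x0, f0) is always a
    candidate, which makes the search monotone under common random
    numbers. Returns (best log10 x, best objective value).
    """
    xs = list(np.linspace(lo_log, hi_log, grid_points))
    cand = [(f0, x0_log)] + [(obj(x), x) for x in xs]
    f_best, x_best = min(cand)
    if refine_iters > 0:
        step = (hi_log - lo_log) / max(grid_points - 1, 1)
        lo_r = max(lo_log, x_best - step)
        hi_r = min(hi_log, x_best + step)
        res = minimize_scalar(obj, bounds=(lo_r, hi_r), method="bounded",
                              options={"maxiter": refine_iters, "xatol": 0.01})
        if res.fun < f_best:
            f_best, x_best = float(res.fun), float(res.x)
    return x_best, f_best


# Each merge time is paired with the migration rates of the pair whose
# gene flow can mimic it (an early merge and high exchange between the
# merging partners are nearly likelihood-equivalent), so the block scans
# the time jointly with a common rate applied to both directions; the
# individual migration passes re-introduce asymmetry afterwards.
_TIME_BLOCKS: dict[str, tuple[str, str]] = {
    "T_1": ("m_pw", "m_wp"),
    "T_2": ("m_ep", "m_pe"),
    "T_3": ("m_we", "m_ew"),
}


def _block_search_2d(obj2, t_lo: float, t_hi: float, m_lo: float, m_hi: float,
                     t0: float, m0: float, f0: float,
                     t_grid: int, m_grid: int, refine_iters: int
                     ) -> tuple[float, float, float]:
    """Joint maximisation over one (merge time, migration rate) ridge.

    ``obj2(t_log, m_log)`` is the negative lnCL; the current point is a
    candidate so the block move is monotone under common random numbers.
    Returns (best t_log, best m_log, best objective).
    """
    ts = np.linspace(t_lo, t_hi, t_grid)
    ms = np.linspace(m_lo, m_hi, m_grid)
    cand = [(f0, t0, m0)]
    for t in ts:
        for m in ms:
            cand.append((obj2(t, m), t, m))
    f_best, t_best, m_best = min(cand)
    if refine_iters > 0:
        t_step = (t_hi - t_lo) / max(t_grid - 1, 1)
        res = minimize_scalar(lambda t: obj2(t, m_best),
                              bounds=(max(t_lo, t_best - t_step),
                                      min(t_hi, t_best + t_step)),
                              method="bounded",
                              options={"maxiter": refine_iters, "xatol": 0.01})
        if res.fun < f_best:
            f_best, t_best = float(res.fun), float(res.x)
    return t_best, m_best, f_best


def _time_bounds(name: str, params: dict[str, float],
                 ranges: dict[str, tuple[float, float]]) -> tuple[float, float]:
    """Search bounds for one merge time, clipped by its neighbours."""
    lo, hi = ranges[name]
    eps = 1.0 + 1e-3
    if name == "T_1":
        hi = min(hi, params["T_2"] / eps)
    elif name == "T_2":
        lo = max(lo, params["T_1"] * eps)
        hi = min(hi, params["T_3"] / eps)
    else:
        lo = max(lo, params["T_2"] * eps)
    return lo, hi


def ecm_fit(
    observed: dict,
    model_id: int,
    *,
    n_anc: float = 60_000.0,
    search_ranges: dict[str, tuple[float, float]] | None = None,
    n_cycles: int = 40,
    n_sims: int = 10_000,
    seed: int = 0,
    init_params: dict[str, float] | None = None,
    tol: float = 0.01,
    grid_points: int = 7,
    refine_iters: int = 4,
    crn_mode: str = "per_cycle",
) -> tuple[dict[str, float], float]:
    """One ECM run: cyclic 1-D maximisation of lnCL in log space.

    Each cycle visits every parameter once, maximising lnCL over that
    parameter with the others held fixed — a coarse log-grid scan of
    ``grid_points`` values followed by ``refine_iters`` bounded Brent
    steps — using a fresh expected-SFS estimate per evaluation under a
    cycle-constant seed (common random numbers: coordinate ascent is
    monotone within a cycle). ``crn_mode="fixed"`` keeps one seed for
    all cycles, making the whole trajectory monotone (useful for
    diagnostics); the default re-draws the seed each cycle to average
    Monte-Carlo error out of the optimum. Stops early when a full cycle
    improves lnCL by less than ``tol``. Returns (fitted parameters,
    last-cycle lnCL).
    """
    ranges = dict(DEFAULT_SEARCH_RANGES)
    if search_ranges:
        ranges.update(search_ranges)
    for k, (lo, hi) in ranges.items():
        if lo >= hi:
            raise InferenceError(f"search range for {k} is inverted")

    sizes = _sizes_from_observed(observed)
    sample_sizes = {p: sizes[p] for p in POPULATIONS if p in sizes}
    if set(sample_sizes) != set(POPULATIONS):
        raise InferenceError("observed spectra must cover all four populations")
    n_poly = sum(s.n_polymorphic for s in observed.values())
    if n_poly <= 0:
        raise InferenceError("observed SFS contains no polymorphic SNPs; "
                             "cannot fit a demographic model")
    pairs = list(observed.keys())

    rng = np.random.default_rng(seed)
    params = dict(init_params) if init_params else _draw_initial_params(rng, ranges)
    cycle_seeds = derive_seeds(seed, max(n_cycles, 1), "ecm-cycles")
    if crn_mode == "fixed":
        cycle_seeds = np.full(max(n_cycles, 1), cycle_seeds[0])
    elif crn_mode != "per_cycle":
        raise ValueError(f"unknown crn_mode {crn_mode!r}")

    def neg_ll(params_now: dict[str, float], eval_seed: int) -> float:
        model = build_model(model_id, params_now, n_anc=n_anc)
        probs = estimate_expected_sfs(model, sample_sizes, n_sims, eval_seed,
                                      pairs=pairs)
        return -composite_log_likelihood(observed, probs)

    last_ll = -np.inf
    for cycle in range(n_cycles):
        eval_seed = int(cycle_seeds[cycle])
        base_ll = -neg_ll(params, eval_seed)
        cur_ll = base_ll
        # sizes, then migration, then merge times: letting migration adapt
        # first keeps recent-merge collapse from masquerading as gene flow
        # when the merge times come up for maximisation
        for name in SIZE_PARAMS + MIGRATION_PARAMS + TIME_PARAMS:
            if name in TIME_PARAMS:
                lo, hi = _time_bounds(name, params, ranges)
                if lo >= hi:
                    continue
                mates = _TIME_BLOCKS[name]
                m_lo, m_hi = ranges[mates[0]]
                m_cur = float(np.sqrt(params[mates[0]] * params[mates[1]]))

                def obj2(t_log: float, m_log: float) -> float:
                    trial = dict(params)
                    trial[name] = 10 ** t_log
                    trial[mates[0]] = 10 ** m_log
                    trial[mates[1]] = 10 ** m_log
                    return neg_ll(trial, eval_seed)

                t_best, m_best, f_best = _block_search_2d(
                    obj2, np.log10(lo), np.log10(hi),
                    np.log10(m_lo), np.log10(m_hi),
                    float(np.log10(np.clip(params[name], lo, hi))),
                    float(np.log10(np.clip(m_cur, m_lo, m_hi))), np.inf,
                    t_grid=grid_points, m_grid=4, refine_iters=refine_iters)
                trial = {**params, name: 10 ** t_best,
                         mates[0]: 10 ** m_best, mates[1]: 10 ** m_best}
                # the symmetric-rate block point may lose to the current
                # asymmetric one: keep whichever scores better
                if -f_best >= cur_ll:
                    params = trial
                    cur_ll = -f_best
                continue

            lo, hi = ranges[name]
            if lo >= hi:
                continue

            def obj(x: float) -> float:
                trial = dict(params)
                trial[name] = 10 ** x
                return neg_ll(trial, eval_seed)

            x_cur = np.log10(np.clip(params[name], lo, hi))
            x_best, f_best = _line_search(obj, np.log10(lo), np.log10(hi),
                                          float(x_cur), -cur_ll,
                                          grid_points, refine_iters)
            # the current point is a candidate under the same seed, so the
            # update can never decrease lnCL within the cycle
            params = {**params, name: 10 ** x_best}
            cur_ll = -f_best
        last_ll = cur_ll
        gain = cur_ll - base_ll
        logger.debug("cycle %d: lnCL %.3f (gain %.3f)", cycle, last_ll, gain)
        if 0 <= gain < tol:
            break
    return params, float(last_ll)


def multi_run_fit(
    observed: dict,
    model_id: int,
    *,
    n_runs: int = 100,
    n_cycles: int = 40,
    n_sims: int = 10_000,
    seed: int = 0,
    n_anc: float = 60_000.0,
    search_ranges: dict[str, tuple[float, float]] | None = None,
    tol: float = 0.01,
    grid_points: int = 7,
    refine_iters: int = 4,
    final_n_sims: int | None = 20_000,
) -> FitResult:
    """Best of ``n_runs`` independently initialised ECM fits.

    The returned FitResult holds the max-lnCL solution and its
    AIC = 2k - 2 lnCL with k = 15 estimated parameters, plus the full
    per-run table. The reported lnCL is re-evaluated at the best
    parameters with ``final_n_sims`` simulations (more than the
    in-search effort): the per-evaluation Monte-Carlo bias of the
    expected SFS depends on where in parameter space it is taken, so
    model comparisons use a common, higher-precision final estimate.
    """
    ranges = dict(DEFAULT_SEARCH_RANGES)
    if search_ranges:
        ranges.update(search_ranges)
    run_seeds = derive_seeds(seed, n_runs, "runs")
    final_seed = int(derive_seeds(seed, 1, "final-ll")[0])
    sizes = _sizes_from_observed(observed)
    sample_sizes = {p: sizes[p] for p in POPULATIONS if p in sizes}
    pairs = list(observed.keys())

    def final_ll(params: dict[str, float]) -> float:
        """Common-seed, higher-precision re-evaluation for run/model ranking."""
        n_eval = max(final_n_sims or 0, n_sims)
        probs = estimate_expected_sfs(build_model(model_id, params, n_anc=n_anc),
                                      sample_sizes, n_eval, final_seed, pairs=pairs)
        return composite_log_likelihood(observed, probs)

    rows = []
    fitted: list[dict[str, float]] = []
    for r in range(n_runs):
        rng = np.random.default_rng(int(run_seeds[r]))
        # stratify T_1 across runs so deep and shallow first merges are
        # both explored regardless of run count
        init = _draw_initial_params(rng, ranges, t1_stratum=(r % n_runs, n_runs))
        params, ll = ecm_fit(observed, model_id, n_anc=n_anc,
                             search_ranges=search_ranges, n_cycles=n_cycles,
                             n_sims=n_sims, seed=int(run_seeds[r]), tol=tol,
                             init_params=init, grid_points=grid_points,
                             refine_iters=refine_iters)
        ll_final = final_ll(params)
        rows.append({"run": r, "ln_cl_search": ll, "ln_cl": ll_final, **params})
        fitted.append(params)
    runs = pd.DataFrame(rows)
    best_idx = int(runs["ln_cl"].idxmax())
    best_params = fitted[best_idx]
    best_ll = float(runs["ln_cl"].iloc[best_idx])
    aic = 2 * N_ESTIMATED_PARAMS - 2 * best_ll
    return FitResult(model_id=model_id, params=best_params, ln_cl=best_ll,
                     aic=aic, n_runs=n_runs, runs=runs,
                     sample_sizes=_sizes_from_observed(observed),
                     n_snps=_observed_snp_total(observed))


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def aic_select(fits: list[FitResult]) -> pd.DataFrame:
    """AIC ranking with delta-AIC and relative likelihoods exp(-dAIC/2).

    All fits must target the same observed data (checked via sample sizes
    and SNP totals).
    """
    if len(fits) < 2:
        raise InferenceError("model selection needs at least two fits")
    ref = fits[0]
    for f in fits[1:]:
        if f.sample_sizes != ref.sample_sizes or not np.isclose(f.n_snps, ref.n_snps):
            raise InferenceError("fits compare different observed datasets")
    df = pd.DataFrame([{"model_id": f.model_id, "ln_cl": f.ln_cl, "aic": f.aic}
                       for f in fits])
    df = df.sort_values("aic", kind="stable").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    df["rel_likelihood"] = np.exp(-df["delta_aic"] / 2.0)
    return df


# ---------------------------------------------------------------------------
# parametric bootstrap
# ---------------------------------------------------------------------------

def percentile_interval(values, alpha: float = 0.05) -> tuple[float, float]:
    """Linear-interpolation percentile interval (alpha/2, 1 - alpha/2)."""
    v = np.asarray(values, dtype=float)
    lo, hi = np.percentile(v, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def parametric_bootstrap(
    model_id: int,
    mle_params: dict[str, float],
    sample_sizes: dict[str, int],
    n_snps: int,
    *,
    n_reps: int = 100,
    n_runs: int = 10,
    n_cycles: int = 20,
    n_sims: int = 10_000,
    seed: int = 0,
    n_anc: float = 60_000.0,
    search_ranges: dict[str, tuple[float, float]] | None = None,
    tol: float = 0.01,
    grid_points: int = 7,
    refine_iters: int = 4,
) -> tuple[dict[str, tuple[float, float]], pd.DataFrame]:
    """Percentile CIs from re-fitting datasets simulated at the MLE.

    Each replicate simulates all pairwise folded spectra with the
    observed SNP count at ``mle_params`` and re-estimates; the 2.5/97.5
    percentiles over successful replicates form the 95% interval. Refits
    default to a reduced effort (10 runs x 20 cycles). Failed replicate
    fits are recorded and skipped, with a warning if fewer than 90%
    succeed; a single replicate yields a degenerate interval (warned).
    """
    model = build_model(model_id, mle_params, n_anc=n_anc)
    rep_seeds = derive_seeds(seed, 2 * n_reps, "bootstrap")
    ss = np.array([sample_sizes[p] for p in POPULATIONS], dtype=np.int64)
    rows = []
    n_fail = 0
    for rep in range(n_reps):
        sim = simulate_sfs(model, ss, int(n_snps), int(rep_seeds[2 * rep]))
        try:
            fit = multi_run_fit(sim, model_id, n_runs=n_runs, n_cycles=n_cycles,
                                n_sims=n_sims, seed=int(rep_seeds[2 * rep + 1]),
                                n_anc=n_anc, search_ranges=search_ranges, tol=tol,
                                grid_points=grid_points, refine_iters=refine_iters)
        except InferenceError as exc:
            n_fail += 1
            logger.warning("bootstrap replicate %d failed: %s", rep, exc)
            continue
        rows.append({"rep": rep, "ln_cl": fit.ln_cl, **fit.params})
    if not rows:
        raise InferenceError("every bootstrap replicate failed")
    if n_fail > 0.1 * n_reps:
        logger.warning("only %d/%d bootstrap replicates succeeded",
                       n_reps - n_fail, n_reps)
    reps = pd.DataFrame(rows)
    if len(reps) == 1:
        logger.warning("single bootstrap replicate: degenerate intervals")
    cis = {k: percentile_interval(reps[k]) for k in PARAM_NAMES}
    return cis, reps
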