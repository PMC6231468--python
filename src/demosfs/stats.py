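"""Per-locality diversity statistics, pairwise F_ST, and PCA.

Statistics follow the standard finite-sample conventions:

* expected heterozygosity He = 1 - sum p_i^2 (biallelic: 2p(1-p)),
* per-site nucleotide diversity pi = n/(n-1) * (1 - sum p_i^2)
  (the unbiased mean pairwise difference),
* F_IS = 1 - H_obs/H_exp averaged over sites with H_exp > 0,
* pairwise F_ST as the two-level Weir-Cockerham-type variance-components
  ("corrected AMOVA") ratio-of-sums estimator across sites,
* PCA on mean-imputed, centred, unit-variance-scaled dosage columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# per-site primitives
# ---------------------------------------------------------------------------

def expected_heterozygosity(allele_freqs) -> float:
    """He = 1 - sum p_i^2 for one site's allele-frequency vector."""
    p = np.asarray(allele_freqs, dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("allele frequencies must sum to 1")
    return float(1.0 - (p ** 2).sum())


def nucleotide_diversity(alt_copies: np.ndarray, n_haplotypes: np.ndarray) -> float:
    """Mean unbiased per-site pi over sites with >= 2 genotyped haplotypes.

    pi_site = n/(n-1) * (1 - p^2 - q^2): the average number of pairwise
    differences per site among the sampled haplotypes.
    """
    alt = np.asarray(alt_copies, dtype=float)
    n = np.asarray(n_haplotypes, dtype=float)
    ok = n >= 2
    if not ok.any():
        return float("nan")
    p = alt[ok] / n[ok]
    h = 1.0 - p ** 2 - (1.0 - p) ** 2
    pi_site = n[ok] / (n[ok] - 1.0) * h
    return float(pi_site.mean())


def inbreeding_coefficient(obs_het: np.ndarray, exp_het: np.ndarray) -> float:
    """Mean of per-site F_IS = 1 - Ho/He over sites with He > 0 (nan if none)."""
    obs = np.asarray(obs_het, dtype=float)
    exp_ = np.asarray(exp_het, dtype=float)
    ok = exp_ > 0
    if not ok.any():
        return float("nan")
    return float((1.0 - obs[ok] / exp_[ok]).mean())


# ---------------------------------------------------------------------------
# per-locality summaries
# ---------------------------------------------------------------------------

@dataclass
class DiversityStats:
    locality_id: str
    n_individuals: int
    h_exp: float
    pi: float
    f_is: float
    replicates: pd.DataFrame | None = None  # per-replicate He/pi/F_IS when subsampled


def _locality_site_stats(g: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-site (alt copies, called haps, Ho, He) for a genotype submatrix."""
    called = g != MISSING
    n_ind = called.sum(axis=0)
    alt = np.where(called, g, 0).sum(axis=0)
    n_hap = 2 * n_ind
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_hap > 0, alt / np.maximum(n_hap, 1), 0.0)
        he = 1.0 - p ** 2 - (1.0 - p) ** 2
        ho = np.where(n_ind > 0,
                      np.where(called, g == 1, False).sum(axis=0) / np.maximum(n_ind, 1),
                      0.0)
    return alt, n_hap, ho, he


def locality_diversity(table: GenotypeTable) -> list[DiversityStats]:
    """He, pi, F_IS per locality, averaged over the table's SNP sites.

    Sites monomorphic *within* a locality still contribute (zeros) — the
    averaging set is the table's retained variant sites, so values are
    comparable across localities sharing the site set.
    """
    out: list[DiversityStats] = []
    for loc in dict.fromkeys(table.locality_ids):
        rows = table.individuals_in_locality(loc)
        g = table.genotypes[rows]
        alt, n_hap, ho, he = _locality_site_stats(g)
        has_data = n_hap >= 2
        out.append(DiversityStats(
            locality_id=loc,
            n_individuals=rows.size,
            h_exp=float(he[has_data].mean()) if has_data.any() else float("nan"),
            pi=nucleotide_diversity(alt, n_hap),
            f_is=inbreeding_coefficient(ho, he),
        ))
    return out


def subsampled_stats(
    table: GenotypeTable,
    n_per_locality: int = 4,
    replicates: int = 20,
    seed: int = 0,
) -> list[DiversityStats]:
    """Replicated equal-n subsampling of individuals per locality.

    Each replicate draws ``n_per_locality`` individuals without replacement
    from every locality and recomputes He/pi/F_IS; localities smaller than
    the target contribute all their individuals (flagged in the log). The
    returned stats carry per-replicate values plus the median as the point
    value.
    """
    rng = np.random.default_rng(seed)
    out: list[DiversityStats] = []
    for loc in dict.fromkeys(table.locality_ids):
        rows = table.individuals_in_locality(loc)
        if rows.size < n_per_locality:
            logger.warning("locality %s has %d < %d individuals; using all",
                           loc, rows.size, n_per_locality)
        rep_rows = []
        for _ in range(replicates):
            if rows.size <= n_per_locality:
                pick = rows
            else:
                pick = rng.choice(rows, size=n_per_locality, replace=False)
            g = table.genotypes[pick]
            alt, n_hap, ho, he = _locality_site_stats(g)
            has_data = n_hap >= 2
            rep_rows.append({
                "h_exp": float(he[has_data].mean()) if has_data.any() else float("nan"),
                "pi": nucleotide_diversity(alt, n_hap),
                "f_is": inbreeding_coefficient(ho, he),
            })
        reps = pd.DataFrame(rep_rows)
        out.append(DiversityStats(
            locality_id=loc,
            n_individuals=min(rows.size, n_per_locality),
            h_exp=float(reps["h_exp"].median()),
            pi=float(reps["pi"].median()),
            f_is=float(reps["f_is"].median()),
            replicates=reps,
        ))
    return out


def diversity_table(stats: list[DiversityStats]) -> pd.DataFrame:
    df = pd.DataFrame([{
        "locality": s.locality_id, "n": s.n_individuals,
        "h_exp": s.h_exp, "pi": s.pi, "f_is": s.f_is,
    } for s in stats])
    return df


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

def _fst_components(alt_a, n_a, alt_b, n_b) -> tuple[np.ndarray, np.ndarray]:
    """Per-site among/total variance components for two samples of gene copies.

    Two-level (populations / gene copies within populations) unbalanced
    one-way ANOVA on allele indicators, the Weir-Cockerham-type estimator
    behind "corrected AMOVA" F_ST:

        MSP = sum_i n_i (p_i - pbar)^2 / (r - 1)
        MSG = sum_i n_i p_i (1 - p_i) / (N - r)
        n_c = (N - sum n_i^2 / N) / (r - 1)
        sigma2_a = (MSP - MSG) / n_c ;  sigma2_w = MSG
    """
    n_a = np.asarray(n_a, float)
    n_b = np.asarray(n_b, float)
    p_a = np.asarray(alt_a, float) / n_a
    p_b = np.asarray(alt_b, float) / n_b
    n_tot = n_a + n_b
    pbar = (alt_a + alt_b) / n_tot
    r = 2
    msp = (n_a * (p_a - pbar) ** 2 + n_b * (p_b - pbar) ** 2) / (r - 1)
    msg = (n_a * p_a * (1 - p_a) + n_b * p_b * (1 - p_b)) / (n_tot - r)
    n_c = (n_tot - (n_a ** 2 + n_b ** 2) / n_tot) / (r - 1)
    sigma_a = (msp - msg) / n_c
    return sigma_a, sigma_a + msg


def pairwise_fst(table: GenotypeTable, group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Multi-locus F_ST between two individual index groups.

    Ratio of sums across sites of among-population over total variance
    components; slightly negative estimates are reported as computed.
    Returns nan when no shared polymorphic site exists.
    """
    if group_a.size < 2 or group_b.size < 2:
        raise ValueError("each group needs at least 2 individuals")
    alt_a, n_a = table.allele_counts(group_a)
    alt_b, n_b = table.allele_counts(group_b)
    ok = (n_a >= 2) & (n_b >= 2)
    alt_tot = alt_a + alt_b
    poly = ok & (alt_tot > 0) & (alt_tot < n_a + n_b)
    if not poly.any():
        return float("nan")
    sigma_a, sigma_t = _fst_components(alt_a[poly], n_a[poly], alt_b[poly], n_b[poly])
    denom = sigma_t.sum()
    if denom == 0:
        return float("nan")
    return float(sigma_a.sum() / denom)


def fst_matrix(table: GenotypeTable, level: str = "population") -> pd.DataFrame:
    """Symmetric pairwise F_ST matrix over populations (or localities)."""
    labels = table.population_ids if level == "population" else table.locality_ids
    if labels is None:
        raise ValueError("table has no population labels")
    labels_arr = np.asarray(labels)
    groups = list(dict.fromkeys(labels))
    mat = pd.DataFrame(np.zeros((len(groups), len(groups))), index=groups, columns=groups)
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            v = pairwise_fst(table, np.flatnonzero(labels_arr == a),
                             np.flatnonzero(labels_arr == b))
            mat.loc[a, b] = mat.loc[b, a] = v
    return mat


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_scores(table: GenotypeTable, n_components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the dosage matrix with mean-frequency imputation of missing data.

    Missing entries are replaced by the per-site mean dosage; columns are
    centred and scaled to unit variance; monomorphic columns are dropped.
    Returns (scores of shape (n_individuals, n_components),
    explained-variance fractions per returned axis).
    """
    if table.n_individuals < 2:
        raise ValueError("PCA needs at least 2 individuals")
    g = table.genotypes.astype(float)
    mask = g == MISSING
    g[mask] = np.nan
    col_mean = np.nanmean(g, axis=0)
    inds = np.where(mask)
    g[inds] = col_mean[inds[1]]
    sd = g.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all sites monomorphic after imputation; PCA undefined")
    x = (g[:, keep] - col_mean[keep]) / sd[keep]
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    ev = s ** 2
    frac = ev / ev.sum()
    k = min(n_components, s.size)
    return u[:, :k] * s[:k], frac[:k]
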