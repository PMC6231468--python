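"""Dataset-construction filters for GBS SNP tables.

Stages, in the order a real pipeline applies them:

1. per-locus Watterson theta and a 95%-quantile whitelist that discards
   hypervariable loci (putative paralog collapses),
2. missingness filters (SNPs with >70% missing genotypes, then
   individuals missing >90% of the surviving sites),
3. one randomly chosen SNP per locus (linkage-equilibrium thinning),
4. a PCA-based outlier-individual report (flags, never deletes —
   outlier removal is an operator decision).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeTable

logger = logging.getLogger(__name__)


class FilterError(RuntimeError):
    """Fatal filtering outcome (e.g. everything removed)."""


@dataclass
class LocusThetaRecord:
    """Watterson theta for one locus: theta_w = S / a_{n-1}."""

    locus_id: str
    s: int              # segregating sites observed at the locus
    n_hap: int          # haplotypes genotyped (median across the locus's sites)
    theta_w: float | None  # None when fewer than 2 haplotypes genotyped


def harmonic_number(n: int) -> float:
    """a_n = sum_{k=1}^{n} 1/k (the Watterson denominator uses a_{n_hap - 1})."""
    return float(sum(1.0 / k for k in range(1, n + 1)))


def per_locus_theta(table: GenotypeTable) -> list[LocusThetaRecord]:
    """Watterson's theta per locus from segregating-site counts.

    S counts the locus's sites at which both alleles are observed among
    non-missing genotypes. n_hap is the floor of the median per-site count
    of non-missing haplotypes; loci with n_hap < 2 get ``theta_w=None``
    and are excluded from downstream quantile computation.
    """
    alt, n_hap_site = table.allele_counts()
    segregating = (alt > 0) & (alt < n_hap_site)
    locus_ids = table.sites["locus_id"].to_numpy()
    records: list[LocusThetaRecord] = []
    for locus in pd.unique(locus_ids):
        idx = np.flatnonzero(locus_ids == locus)
        s = int(segregating[idx].sum())
        n_hap = int(math.floor(np.median(n_hap_site[idx])))
        if n_hap < 2:
            records.append(LocusThetaRecord(locus, s, n_hap, None))
            continue
        a = harmonic_number(n_hap - 1)
        records.append(LocusThetaRecord(locus, s, n_hap, s / a))
    return records


def whitelist_by_quantile(records: list[LocusThetaRecord], q: float = 0.95) -> set[str]:
    """Loci with theta <= the q-quantile (linear-interpolation quantile).

    Loci strictly above the cutoff (hypervariable) are excluded; flagged
    records (theta undefined) do not enter the quantile but are retained
    in the whitelist (no evidence against them).
    """
    valid = [r for r in records if r.theta_w is not None]
    if not valid:
        raise FilterError("no locus with a defined theta; cannot build whitelist")
    thetas = np.array([r.theta_w for r in valid])
    cutoff = float(np.quantile(thetas, q))
    kept = {r.locus_id for r in valid if r.theta_w <= cutoff}
    kept |= {r.locus_id for r in records if r.theta_w is None}
    n_excluded = len(records) - len(kept)
    logger.info("theta whitelist: cutoff %.4g, %d/%d loci retained (%d excluded)",
                cutoff, len(kept), len(records), n_excluded)
    return kept


def apply_whitelist(table: GenotypeTable, whitelist: set[str]) -> GenotypeTable:
    """Keep only sites whose locus is in the whitelist."""
    keep = table.sites["locus_id"].isin(whitelist).to_numpy()
    return table.take_sites(np.flatnonzero(keep))


def write_whitelist(whitelist: set[str], path) -> None:
    with open(path, "w") as fh:
        for locus in sorted(whitelist):
            fh.write(locus + "\n")


def filter_missingness(
    table: GenotypeTable,
    snp_max_missing: float = 0.70,
    ind_max_missing: float = 0.90,
) -> tuple[GenotypeTable, dict[str, int]]:
    """Drop SNPs with missing fraction > snp_max_missing, then individuals
    whose missing fraction over the *surviving* sites is > ind_max_missing.

    Both rules are strict inequalities. Returns the filtered table and the
    counts of dropped sites/individuals.
    """
    if not (0 < snp_max_missing <= 1 and 0 < ind_max_missing <= 1):
        raise ValueError("missingness thresholds must lie in (0, 1]")
    missing = table.genotypes == MISSING
    site_frac = missing.mean(axis=0)
    keep_sites = np.flatnonzero(site_frac <= snp_max_missing)
    if keep_sites.size == 0:
        raise FilterError("all SNPs exceed the missingness threshold")
    out = table.take_sites(keep_sites)
    ind_frac = (out.genotypes == MISSING).mean(axis=1)
    keep_inds = np.flatnonzero(ind_frac <= ind_max_missing)
    if keep_inds.size == 0:
        raise FilterError("all individuals exceed the missingness threshold")
    out = out.take_individuals(keep_inds)
    report = {
        "sites_dropped": table.n_sites - keep_sites.size,
        "individuals_dropped": table.n_individuals - keep_inds.size,
    }
    logger.info("missingness filter: dropped %d sites, %d individuals",
                report["sites_dropped"], report["individuals_dropped"])
    return out, report


def one_snp_per_locus(table: GenotypeTable, seed: int) -> GenotypeTable:
    """Retain exactly one uniformly chosen SNP per locus (seeded, deterministic)."""
    rng = np.random.default_rng(seed)
    locus_ids = table.sites["locus_id"].to_numpy()
    chosen: list[int] = []
    for locus in pd.unique(locus_ids):
        idx = np.flatnonzero(locus_ids == locus)
        chosen.append(int(idx[rng.integers(idx.size)]))
    chosen.sort()
    return table.take_sites(chosen)


def pca_outlier_report(table: GenotypeTable, k: float = 6.0) -> pd.DataFrame:
    """Flag individuals > k robust-MADs from the PC1-2 centroid.

    Mirrors the iterative PCA + filter workflow used to spot library
    artifacts; outliers are reported for the operator, not deleted.
    """
    from .stats import pca_scores

    scores, _ = pca_scores(table, n_components=2)
    centre = np.median(scores, axis=0)
    dist = np.sqrt(((scores - centre) ** 2).sum(axis=1))
    mad = np.median(np.abs(dist - np.median(dist))) * 1.4826
    scale = mad if mad > 0 else (dist.std() or 1.0)
    z = (dist - np.median(dist)) / scale
    return pd.DataFrame({
        "individual": table.individual_ids,
        "locality": table.locality_ids,
        "pc_distance": dist,
        "robust_z": z,
        "outlier": z > k,
    })
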