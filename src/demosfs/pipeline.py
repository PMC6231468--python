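"""End-to-end pipeline: read -> filter -> stats -> SFS -> fit -> select -> bootstrap.

Configuration defaults reproduce the motivating analysis's settings (95% theta
whitelist, >70%/>90% missingness cutoffs, 4-individual x 20-replicate
subsampling, 13/13/24/22 minimum individuals per population, mu = 7e-9,
g = 1 year, N_ANC = 60,000, 100 runs x 40 ECM cycles x 200,000
simulations, 100 bootstrap replicates); every value can be overridden
in a YAML config. A single root seed fans out into named per-stage
substreams, so stages are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .coalsim import derive_seeds, simulate_genotypes_with_missingness
from .demography import MODEL3_POINT_ESTIMATES, POPULATIONS, build_model
from .filtering import (apply_whitelist, filter_missingness, one_snp_per_locus,
                        pca_outlier_report, per_locus_theta, whitelist_by_quantile,
                        write_whitelist)
from .genotypes import GenotypeTable, PopulationMap, read_vcf, write_structure_file
from .inference import aic_select, multi_run_fit, parametric_bootstrap
from .sfs import all_pairs, build_pairwise_sfs
from .stats import diversity_table, fst_matrix, locality_diversity, subsampled_stats

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All pipeline settings; defaults follow the motivating analysis."""

    # inputs (either a VCF + population map, or simulate=True)
    vcf: str | None = None
    population_map: str | None = None
    simulate: bool = False
    sim_model_id: int = 3
    sim_params: dict = field(default_factory=lambda: dict(MODEL3_POINT_ESTIMATES))
    sim_diploids_per_pop: int = 8
    sim_n_loci: int = 2000
    sim_snps_per_locus: int = 3
    sim_missing_rate: float = 0.2

    # filtering
    theta_quantile: float = 0.95
    snp_max_missing: float = 0.70
    ind_max_missing: float = 0.90

    # diversity statistics
    n_per_locality: int = 4
    subsample_replicates: int = 20

    # SFS construction (minimum individuals per population)
    min_individuals: dict = field(default_factory=lambda: {
        "WAS": 13, "EGB": 13, "PW": 24, "WGB": 22})

    # demographic inference
    mu: float = 7e-9
    gen_time: float = 1.0
    n_anc: float = 60_000.0
    fit_models: tuple = (1, 2, 3)
    n_runs: int = 100
    n_cycles: int = 40
    n_sims: int = 200_000
    bootstrap_reps: int = 100
    bootstrap_runs: int = 10
    bootstrap_cycles: int = 20

    # run settings
    seed: int = 0
    outdir: str = "demosfs_out"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["fit_models"] = list(d["fit_models"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_input(config: PipelineConfig) -> GenotypeTable:
    """Stage 0: read the VCF + population map, or simulate a dataset."""
    if config.simulate:
        model = build_model(config.sim_model_id, config.sim_params,
                            n_anc=config.n_anc, mu=config.mu,
                            gen_time=config.gen_time)
        seed = int(derive_seeds(config.seed, 1, "simulate")[0])
        return simulate_genotypes_with_missingness(
            model, [config.sim_diploids_per_pop] * 4, config.sim_n_loci,
            config.sim_snps_per_locus, config.sim_missing_rate, seed,
            locality_size=config.n_per_locality)
    if not config.vcf or not config.population_map:
        raise PipelineError("config needs either simulate=true or both "
                            "'vcf' and 'population_map' paths")
    for p in (config.vcf, config.population_map):
        if not Path(p).exists():
            raise PipelineError(f"input path does not exist: {p}")
    popmap = PopulationMap.from_table(config.population_map)
    return read_vcf(config.vcf, popmap)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; write artifacts + manifest to config.outdir.

    Returns a summary report dict (also serialised as report.json).
    Stage failures abort with a stage-tagged diagnostic; artifacts
    already written are left in place.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    stage = "input"
    try:
        table = load_input(config)
        report["stages"]["input"] = {
            "individuals": table.n_individuals, "sites": table.n_sites}

        stage = "whitelist"
        records = per_locus_theta(table)
        whitelist = whitelist_by_quantile(records, config.theta_quantile)
        write_whitelist(whitelist, out / "whitelist.txt")
        table = apply_whitelist(table, whitelist)
        report["stages"]["whitelist"] = {
            "loci_retained": len(whitelist), "sites_after": table.n_sites}

        stage = "missingness"
        table, counts = filter_missingness(table, config.snp_max_missing,
                                           config.ind_max_missing)
        report["stages"]["missingness"] = {
            **counts, "individuals_after": table.n_individuals,
            "sites_after": table.n_sites}
        write_structure_file(table, out / "filtered.str")
        outliers = pca_outlier_report(table)
        outliers.to_csv(out / "pca_outliers.tsv", sep="\t", index=False)

        stage = "stats"
        div = diversity_table(locality_diversity(table))
        div.to_csv(out / "diversity.tsv", sep="\t", index=False)
        sub_seed = int(derive_seeds(config.seed, 1, "subsample")[0])
        sub = diversity_table(subsampled_stats(
            table, config.n_per_locality, config.subsample_replicates, sub_seed))
        sub.to_csv(out / "diversity_subsampled.tsv", sep="\t", index=False)
        fst = fst_matrix(table)
        fst.to_csv(out / "fst_matrix.tsv", sep="\t")
        report["stages"]["stats"] = {
            "localities": len(div),
            "max_pairwise_fst": float(np.nanmax(fst.to_numpy()))}

        stage = "sfs"
        thin_seed = int(derive_seeds(config.seed, 1, "thin")[0])
        thinned = one_snp_per_locus(table, thin_seed)
        pops = [p for p in POPULATIONS if p in set(thinned.population_ids or [])]
        observed = {}
        for a, b in all_pairs(pops):
            sfs = build_pairwise_sfs(thinned, a, b, config.min_individuals)
            sfs.to_text(out / f"sfs_{a}_{b}.txt")
            observed[(a, b)] = sfs
        report["stages"]["sfs"] = {
            "pairs": len(observed),
            "snps_thinned": thinned.n_sites,
            "polymorphic_mass": {f"{a}-{b}": s.n_polymorphic
                                 for (a, b), s in observed.items()}}

        stage = "fit"
        fit_seeds = derive_seeds(config.seed, len(config.fit_models), "fit")
        fits = []
        for i, mid in enumerate(config.fit_models):
            fit = multi_run_fit(observed, mid, n_runs=config.n_runs,
                                n_cycles=config.n_cycles, n_sims=config.n_sims,
                                seed=int(fit_seeds[i]), n_anc=config.n_anc)
            fit.runs.to_csv(out / f"fit_model{mid}_runs.tsv", sep="\t", index=False)
            fits.append(fit)
        report["stages"]["fit"] = {
            f"model{f.model_id}": {"ln_cl": f.ln_cl, "aic": f.aic,
                                   "params": f.params}
            for f in fits}

        stage = "select"
        ranking = aic_select(fits)
        ranking.to_csv(out / "model_selection.tsv", sep="\t", index=False)
        best = fits[int(np.argmin([f.aic for f in fits]))]
        report["stages"]["select"] = {
            "best_model": int(best.model_id),
            "ranking": ranking.to_dict(orient="records")}

        stage = "bootstrap"
        if config.bootstrap_reps > 0:
            bs_seed = int(derive_seeds(config.seed, 1, "bootstrap")[0])
            cis, reps = parametric_bootstrap(
                best.model_id, best.params, best.sample_sizes,
                int(round(best.n_snps)), n_reps=config.bootstrap_reps,
                n_runs=config.bootstrap_runs, n_cycles=config.bootstrap_cycles,
                n_sims=config.n_sims, seed=bs_seed, n_anc=config.n_anc)
            reps.to_csv(out / "bootstrap_replicates.tsv", sep="\t", index=False)
            with open(out / "bootstrap_ci.json", "w") as fh:
                json.dump({k: list(v) for k, v in cis.items()}, fh, indent=2)
            report["stages"]["bootstrap"] = {
                "reps": len(reps), "ci": {k: list(v) for k, v in cis.items()}}
    except Exception as exc:
        raise PipelineError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "config": yaml.safe_load(yaml.safe_dump(
            {**dataclasses.asdict(config),
             "fit_models": list(config.fit_models)})),
        "inputs": {p: _checksum(p) for p in (config.vcf, config.population_map)
                   if p and Path(p).exists()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
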