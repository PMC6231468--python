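"""Genotype containers and I/O.

The central in-memory object is :class:`GenotypeTable`: a dense
individuals x sites matrix of alt-allele dosages (0, 1, 2) for diploid
biallelic SNPs, with an explicit missing sentinel, per-site locus IDs
(GBS stacks/loci) and per-individual locality and population labels.

Supported external formats:

* VCF 4.x (read via cyvcf2, written as minimal text) — one diploid GT
  per individual per site; multiallelic and non-SNP records are skipped.
* STRUCTURE two-row-per-individual text (missing allele = -9).
* Population map: tab-separated ``individual  locality  population``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing diploid genotype. Never 0 — dosage 0 is HOM-REF.
MISSING: int = -1


class GenotypeIOError(RuntimeError):
    """Fatal problem reading or interpreting genotype data."""


@dataclass
class PopulationMap:
    """individual -> locality -> population assignments.

    Localities partition individuals; populations partition localities.
    """

    individual_to_locality: dict[str, str]
    locality_to_population: dict[str, str]

    def locality(self, individual: str) -> str:
        try:
            return self.individual_to_locality[individual]
        except KeyError:
            raise GenotypeIOError(f"individual {individual!r} not in population map")

    def population(self, individual: str) -> str:
        return self.locality_to_population[self.locality(individual)]

    @classmethod
    def from_table(cls, path: str | Path) -> "PopulationMap":
        """Read a tab-separated table with columns individual, locality, population."""
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["individual", "locality", "population"],
                         dtype=str, comment="#")
        if df.isnull().any().any():
            raise GenotypeIOError(f"population map {path} has incomplete rows")
        ind2loc = dict(zip(df["individual"], df["locality"]))
        loc2pop: dict[str, str] = {}
        for loc, pop in zip(df["locality"], df["population"]):
            if loc in loc2pop and loc2pop[loc] != pop:
                raise GenotypeIOError(
                    f"locality {loc!r} assigned to two populations "
                    f"({loc2pop[loc]!r}, {pop!r})")
            loc2pop[loc] = pop
        return cls(ind2loc, loc2pop)

    def to_table(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for ind, loc in self.individual_to_locality.items():
                fh.write(f"{ind}\t{loc}\t{self.locality_to_population[loc]}\n")


@dataclass
class GenotypeTable:
    """Diploid biallelic SNP genotypes as alt-allele dosage.

    Attributes
    ----------
    genotypes
        int8 array of shape (n_individuals, n_sites); entries in
        {0, 1, 2, MISSING}.
    individual_ids, locality_ids, population_ids
        Per-individual labels (population_ids may be None).
    sites
        DataFrame with columns ``locus_id`` (str) and ``pos``
        (0-based int position within the locus).
    """

    genotypes: np.ndarray
    individual_ids: list[str]
    locality_ids: list[str]
    sites: pd.DataFrame
    population_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n_ind, n_sites = self.genotypes.shape
        if len(self.individual_ids) != n_ind or len(self.locality_ids) != n_ind:
            raise ValueError("individual label lists do not match matrix rows")
        if len(self.sites) != n_sites:
            raise ValueError("site table does not match matrix columns")
        if self.population_ids is not None and len(self.population_ids) != n_ind:
            raise ValueError("population label list does not match matrix rows")
        bad = (self.genotypes > 2) | ((self.genotypes < 0) & (self.genotypes != MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or MISSING (diploid only)")
        self.sites = self.sites.reset_index(drop=True)

    # -- basic shape/masks -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def called_mask(self) -> np.ndarray:
        """Boolean matrix: True where the genotype is not missing."""
        return self.genotypes != MISSING

    def allele_counts(self, rows: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt copies, called haplotypes) over the given rows (default all)."""
        g = self.genotypes if rows is None else self.genotypes[rows]
        called = g != MISSING
        alt = np.where(called, g, 0).sum(axis=0)
        return alt.astype(np.int64), 2 * called.sum(axis=0).astype(np.int64)

    # -- subsetting --------------------------------------------------------

    def take_individuals(self, idx: Sequence[int] | np.ndarray) -> "GenotypeTable":
        idx = np.asarray(idx)
        return GenotypeTable(
            self.genotypes[idx],
            [self.individual_ids[i] for i in idx],
            [self.locality_ids[i] for i in idx],
            self.sites.copy(),
            [self.population_ids[i] for i in idx] if self.population_ids else None,
        )

    def take_sites(self, idx: Sequence[int] | np.ndarray) -> "GenotypeTable":
        idx = np.asarray(idx)
        return GenotypeTable(
            self.genotypes[:, idx],
            list(self.individual_ids),
            list(self.locality_ids),
            self.sites.iloc[idx].reset_index(drop=True),
            list(self.population_ids) if self.population_ids else None,
        )

    def individuals_in_population(self, population: str) -> np.ndarray:
        if self.population_ids is None:
            raise ValueError("table has no population labels")
        return np.flatnonzero(np.asarray(self.population_ids) == population)

    def individuals_in_locality(self, locality: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.locality_ids) == locality)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    population_map: PopulationMap | None = None,
    locus_from: str | Callable[[str, str], str] = "chrom",
) -> GenotypeTable:
    """Read diploid biallelic SNPs from a VCF into a GenotypeTable.

    Unphased and phased genotypes are treated identically (dosage coding);
    multiallelic and non-SNP records are skipped with a warning giving the
    count. ``locus_from`` sets the locus-ID convention: ``"chrom"`` (the
    CHROM field is the GBS locus, the default for stacks-style VCFs),
    ``"id"`` (the ID column), or a callable ``f(chrom, vcf_id) -> locus_id``.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 raises various types
        raise GenotypeIOError(f"cannot read VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    if locus_from == "chrom":
        extract = lambda chrom, vid: chrom
    elif locus_from == "id":
        extract = lambda chrom, vid: vid
    elif callable(locus_from):
        extract = locus_from
    else:
        raise ValueError(f"unknown locus_from rule {locus_from!r}")

    columns: list[np.ndarray] = []
    locus_ids: list[str] = []
    positions: list[int] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
        gt = var.gt_types
        dosage = np.empty(len(samples), dtype=np.int8)
        dosage[gt == 0] = 0
        dosage[gt == 1] = 1
        dosage[gt == 3] = 2
        dosage[gt == 2] = MISSING
        columns.append(dosage)
        locus_ids.append(extract(var.CHROM, var.ID))
        positions.append(var.POS - 1)  # VCF POS is 1-based
    vcf.close()

    if n_skipped:
        warnings.warn(f"skipped {n_skipped} multiallelic/non-SNP records in {path}")
        logger.warning("skipped %d multiallelic/non-SNP records", n_skipped)
    if not columns:
        raise GenotypeIOError(f"no parseable biallelic SNP records in {path}")

    genotypes = np.column_stack(columns)
    sites = pd.DataFrame({"locus_id": locus_ids, "pos": positions})
    if population_map is not None:
        locality = [population_map.locality(s) for s in samples]
        population = [population_map.population(s) for s in samples]
    else:
        locality = ["."] * len(samples)
        population = None
    logger.info("read %d individuals x %d sites from %s",
                genotypes.shape[0], genotypes.shape[1], path)
    return GenotypeTable(genotypes, samples, locality, sites, population)


def write_vcf(table: GenotypeTable, path: str | Path) -> None:
    """Write a minimal VCF 4.2 text file (CHROM = locus_id, POS 1-based).

    Alleles are written as generic A (REF) / T (ALT); the table carries no
    nucleotide identities. Round-trips through :func:`read_vcf`.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.individual_ids) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        g = table.genotypes
        for j in range(table.n_sites):
            locus = table.sites["locus_id"].iat[j]
            pos = int(table.sites["pos"].iat[j]) + 1
            cells = "\t".join(gt_str[int(g[i, j])] for i in range(table.n_individuals))
            fh.write(f"{locus}\t{pos}\t{locus}_{pos}\tA\tT\t.\tPASS\t.\tGT\t{cells}\n")


# ---------------------------------------------------------------------------
# STRUCTURE format
# ---------------------------------------------------------------------------

def write_structure_file(table: GenotypeTable, path: str | Path) -> None:
    """Write STRUCTURE text: two rows per individual (one allele per row).

    Columns: individual label, locality label, then one allele (0/1) per
    site; missing genotypes encoded as -9 on both rows. Dosage d is
    decomposed as d = a1 + a2 with a1 <= a2 (phase is not represented).
    """
    if table.n_individuals == 0 or table.n_sites == 0:
        raise GenotypeIOError("refusing to write an empty STRUCTURE file")
    decomp = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (-9, -9)}
    with open(path, "w") as fh:
        for i, ind in enumerate(table.individual_ids):
            rows: tuple[list[int], list[int]] = ([], [])
            for j in range(table.n_sites):
                a1, a2 = decomp[int(table.genotypes[i, j])]
                rows[0].append(a1)
                rows[1].append(a2)
            for alleles in rows:
                fh.write("\t".join([ind, table.locality_ids[i]]
                                   + [str(a) for a in alleles]) + "\n")


def read_structure_file(
    path: str | Path,
    sites: pd.DataFrame | None = None,
    population_map: PopulationMap | None = None,
) -> GenotypeTable:
    """Companion reader for :func:`write_structure_file`.

    ``sites`` restores locus IDs / positions; without it sites are labelled
    ``site_0 .. site_{n-1}`` each as its own locus.
    """
    inds: list[str] = []
    locs: list[str] = []
    dosages: list[np.ndarray] = []
    pending: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            ind, loc = parts[0], parts[1]
            alleles = np.array([int(x) for x in parts[2:]], dtype=np.int8)
            if ind not in pending:
                pending[ind] = alleles
                inds.append(ind)
                locs.append(loc)
            else:
                first = pending.pop(ind)
                d = first + alleles
                d[(first == -9) | (alleles == -9)] = MISSING
                dosages.append(d)
    if pending:
        raise GenotypeIOError(f"odd number of allele rows for {sorted(pending)}")
    genotypes = np.vstack(dosages)
    if sites is None:
        sites = pd.DataFrame({"locus_id": [f"site_{j}" for j in range(genotypes.shape[1])],
                              "pos": np.zeros(genotypes.shape[1], dtype=int)})
    pops = [population_map.population(i) for i in inds] if population_map else None
    return GenotypeTable(genotypes, inds, locs, sites, pops)
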