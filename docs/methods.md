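# Methods

`demosfs` implements a population-genetic analysis pipeline for
reduced-representation (GBS/RADseq) SNP data: dataset-construction
filters, per-locality diversity statistics, folded pairwise joint site
frequency spectra (SFS), and simulation-based composite-likelihood
inference of four-population divergence/migration histories with AIC
model selection and parametric-bootstrap confidence intervals. This
note records the model, the estimators, the numerical choices, and the
limits of what the package's synthetic tests demonstrate.

## Data model

Genotypes are diploid biallelic SNP dosages (0/1/2 copies of the
alternate allele) with an explicit missing sentinel, organised as
individuals x sites with a locus ID per site (a GBS locus is a short
assembled stack; several SNPs may share a locus). Individuals carry a
sampling-locality label and a population label; populations partition
localities. Heterozygote phase is never used. Multiallelic records and
indels are excluded at VCF ingestion.

## Dataset-construction filters

1. **Hypervariable-locus whitelist.** Per locus, Watterson's
   `theta_W = S / a`, where `S` is the number of segregating sites
   observed at the locus and `a = sum_{k=1}^{n-1} 1/k` with `n` the
   number of genotyped haplotypes. Because missingness varies site to
   site within a locus, `n` is taken as the floor of the median
   per-site genotyped-haplotype count — robust to sporadic dropouts,
   and the floor keeps the harmonic sum well defined when the median is
   a half-integer. Loci with `theta_W` above the 95% linear-interpolation
   quantile are removed: in GBS assemblies an excess of segregating
   sites on one locus is more often a collapsed paralog than real
   variation. Loci with fewer than two genotyped haplotypes are flagged,
   excluded from the quantile, and retained (no evidence against them).
2. **Missingness.** Sites with more than 70% missing genotypes are
   dropped first; then individuals missing more than 90% of the
   surviving sites. Both rules are strict inequalities, and the
   individual fraction is computed on the filtered site set, matching
   the order in which a GBS filtering workflow applies them.
3. **Linkage-equilibrium thinning.** One SNP per locus, chosen
   uniformly at random under a seed, because the composite likelihood
   treats SNPs as independent draws.
4. **PCA outlier report.** PCA on the dosage matrix with missing
   entries imputed by the per-site mean dosage, columns centred and
   scaled to unit variance. Individuals further than k (default 6)
   robust MADs from the PC1-2 centroid are flagged for the operator —
   outlier removal in practice is iterative and manual, so
   the package reports rather than deletes.

## Diversity statistics and F_ST

Per locality, over the table's retained variant sites: expected
heterozygosity `He = 1 - sum p_i^2`; unbiased per-site nucleotide
diversity `pi = n/(n-1) (1 - sum p_i^2)` (the mean number of pairwise
differences among sampled haplotypes), excluding sites with fewer than
two genotyped haplotypes; and `F_IS = 1 - Ho/He` averaged over sites
with `He > 0`. Sites monomorphic within a locality contribute zeros, so
values are comparable across localities sharing a site set; the
absolute scale refers to variant sites only (no per-locus length
remains after thinning, so a per-base pi is not computable).
Equal-sample-size comparisons are supported by repeated subsampling
(default 4 individuals per locality, 20 replicates, medians reported).

Pairwise population F_ST is the two-level variance-components
estimator — the standard reading of "corrected AMOVA F_ST": per site,
an unbalanced one-way ANOVA on allele indicators over gene copies
yields an among-population component `sigma_a^2 = (MSP - MSG)/n_c` and
a within component `MSG`; the multi-locus estimate is the ratio of sums
`sum sigma_a^2 / sum (sigma_a^2 + MSG)` across polymorphic shared
sites. Negative estimates are reported as computed, not truncated.

## Folded pairwise joint SFS

For each population pair, a site genotyped in at least the configured
minimum number of individuals in *both* populations (defaults 13 WAS,
13 EGB, 24 P/W, 22 WGB) is projected down to exactly twice that many
haplotypes per population by hypergeometric expectation — entry `m` of
the projection of `k` alternate copies among `n_from` haplotypes to
`n_to` is `C(k,m) C(n_from-k, n_to-m) / C(n_from, n_to)` — which
removes all missing data deterministically while using every retained
site (the average over all random subsamples rather than a single
draw). The two per-population projections combine as an outer product
and the mass is folded: configuration `(i, j)` maps to
`(nA-i, nB-j)` when the pooled count exceeds half the pooled sample
size; at exactly half, the lexicographically smaller representative is
kept (deterministic and involution-safe). The `(0,0)` corner — sites
monomorphic in the pair after projection, into which the doubly-fixed
corner also folds — is masked out of the likelihood, which is fitted to
polymorphic spectra only. Projected fractional mass stays fractional.

## Structured-coalescent simulator

The simulator is a continuous-time structured coalescent over demes:
within a deme holding `k` lineages of size `N` diploids, coalescence at
rate `k(k-1)/2 / (2N)` per generation; per-lineage backward migration
at constant rates while both partner demes exist; instantaneous deme
merges at the model's times, after which migration involving either
deme ceases. Times are generations, sizes diploids. Each SNP lives on
its own independent genealogy (free recombination between SNPs,
matching the one-SNP-per-locus thinning); there is no within-locus
recombination, selection, or sequencing error.

**Conditioning on polymorphism.** Under infinite sites with a small
mutation rate, a genealogy carries a segregating site with probability
proportional to its total branch length, and the site's frequency
configuration is that of the mutated branch. Both uses of the engine
respect this weighting:

* *Expected SFS* — every branch of every simulated genealogy
  contributes its length to its descendant-count configuration; the
  normalised accumulation estimates `E[l_config] / E[L]`, the expected
  folded joint SFS conditional on polymorphism. This branch-weighted
  estimator has far lower variance per genealogy than sampling a single
  mutation, which is what makes simulation-based fitting tractable on
  one CPU.
* *Data generation* — SNPs are drawn from the pooled branches of all
  simulated genealogies with probability proportional to branch length.
  Sampling one mutation per tree instead would produce the subtly
  different distribution `E[l_config / L_tree]` (it ignores that longer
  trees are likelier to be hit); the discrepancy is ~3% on a folded
  n=4 spectrum and was caught by the closed-form `1/i` oracle.

The engine is cross-validated in the test suite against closed forms
(`E[TMRCA] = 2N` and `E[pi] = 4N mu` for n=2; isolation divergence
`4 N_anc mu + 2 T mu`) and against msprime's branch-mode allele
frequency spectrum under the full four-population Model 3 history.

Genotype-table generation pairs haplotypes into diploids, groups SNPs
into loci (grouping labels only — SNPs remain independent), masks each
genotype independently at the requested missingness rate, and splits
each population into localities of configurable size. Carrier sets use
64-bit masks, so genotype simulation supports up to 64 haplotypes in
total; SFS-only simulation has no such limit.

## The three four-population histories

Four extant populations — WAS (Wasatch), EGB (Eastern Great Basin), PW
(Palouse/Wallowa), WGB (Western Great Basin) — with 15 estimated
parameters shared by all three topologies: present sizes `N_WAS, N_EGB,
N_PW, N_WGB`, intermediate ancestor sizes `N_1, N_2`, merge times
`T_1 < T_2 < T_3` (generations), and six pairwise migration rates on
the `2Nm` scale between adjacent pairs (WAS-EGB, EGB-PW, PW-WGB). The
ancestral size `N_ANC` is fixed, never estimated, at
`theta_pi / 2 / (mu g)` = 60,000 for `theta_pi = 8.4e-4`, `mu = 7e-9`
per site per generation and `g = 1` year.

* Model 1 (tree): (PW,WGB) merge at `T_1` into `N_1`; (WAS,EGB) at
  `T_2` into `N_2`; root at `T_3`.
* Model 2 (chain, east first): (WAS,EGB) at `T_1`; +PW at `T_2`;
  +WGB at `T_3`.
* Model 3 (chain, WAS deepest): (PW,WGB) at `T_1`; +EGB at `T_2`;
  +WAS at `T_3`.

Migration subscripts are read first-index -> second-index backward in
time ((we,ew) for WAS-EGB, (ep,pe) for EGB-PW, (pw,wp) for PW-WGB), and
`2Nm` is unscaled by the present size of the first-subscript deme —
the deme whose lineages move backward. No single convention is
standard, so this one is documented here and the conversion function
accepts any deme size. Rates are constant while
both partners exist and asymmetric rates are allowed (the source
figures assume directionally similar rates, but the reported tables are
asymmetric; the package estimates both directions).

## Composite likelihood and ECM optimisation

The composite log-likelihood is
`lnCL = sum_pairs sum_entries m_e ln p_e` over unmasked folded entries
of all six pairwise spectra, with `p` the simulated expected SFS
renormalised over unmasked entries. Expected-SFS cells with zero
simulated mass receive the floor `p_min = 0.1 / n_sims` (then
renormalised) so lnCL stays finite. lnCL is reported in natural log
with a log10 view for comparison with tools that print log10
likelihoods. SNPs polymorphic overall but monomorphic within a pair
fall in that pair's masked corner and drop out, mirroring the
polymorphic-only fit.

Because every likelihood evaluation is a Monte-Carlo estimate,
optimisation uses expectation-conditional-maximisation cycles with
common random numbers: within a cycle all evaluations share one seed,
so conditional maximisations are comparable and the cycle is monotone;
the seed is refreshed between cycles so the optimum is not tied to one
noise realisation (a diagnostic mode keeps a single seed throughout,
making the whole trajectory provably monotone). One cycle visits:

1. the six population sizes, each by a 1-D search in log space (coarse
   log-grid scan, then bounded Brent refinement — slices of a composite
   likelihood along one parameter are often multimodal, so a purely
   local search is not safe);
2. the six migration rates, likewise;
3. the three merge times, each jointly with a common rate applied to
   both directions of its partner pair's migration — (T_1 with PW-WGB,
   T_2 with EGB-PW, T_3 with WAS-EGB) — as a 2-D block. An early merge
   and strong gene flow between the merging partners are nearly
   likelihood-equivalent, so these ridges must be navigated jointly;
   the individual migration passes restore asymmetry afterwards.
   Time bounds are clipped by the neighbouring times to preserve
   `T_1 < T_2 < T_3`.

Sizes and migration precede times within the cycle: letting gene flow
adapt first prevents a recent-merge collapse from masquerading as the
only explanation of between-population similarity when the times are
first maximised.

Runs start from random log-uniform points. Merge times are drawn
sequentially (T_1 anywhere in its range, T_2 above it, T_3 above that)
rather than as the sorted triple of independent draws — sorting puts
T_1 at the minimum of three uniforms and starves the multistart of
deep-first-merge starts — and T_1 is additionally stratified across
runs (run r draws from the r-th of n_runs equal log-width strata), a
Latin-hypercube-style guarantee that shallow and deep first merges are
both explored at any run count. Initial migration draws are confined
to the moderate range 2Nm in [0.1, 10] (the search range stays
[1e-3, 1e2]): starting a run at an extreme rate makes the first
cycle's time searches collapse toward degenerate histories.

After all runs, each run's final parameters are re-evaluated at a
common seed with a larger simulation count (default 20,000 genealogies)
and the best run is chosen on that value: the Monte-Carlo bias of a
cheap expected-SFS estimate depends on where in parameter space it is
taken, so run and model comparisons must not ride on in-search values.
AIC = `2k - 2 lnCL` with `k = 15` uses the re-evaluated lnCL, and model
ranking reports `exp(-dAIC/2)` relative likelihoods.

Parametric bootstrap re-simulates all six spectra at the fitted
parameters with the observed SNP total, refits each replicate at
reduced effort (default 10 runs x 20 cycles), and reports 2.5/97.5
linear-interpolation percentiles over successful replicates (failures
are logged; a warning fires below 90% success).

## Problem sizes used by the tests and acceptance script

Full-scale settings (100 runs x 40 cycles x 200,000 simulations per
evaluation, 100 bootstrap replicates) are the package defaults and are
what a real analysis should use; they take hours to days of CPU. The
test suite and the acceptance script exercise the machinery at reduced
scale, chosen as follows and fixed before any results were read off:

* recovery check: data simulated under Model 3 at its published point
  estimates, 8 diploids per population, 2,000 SNPs; fit with 3 runs x
  5 cycles, 1,000 genealogies per in-search evaluation, 20,000 for
  final re-evaluations;
* model selection: 10 replicate datasets at the same scale, fits with
  200 genealogies per evaluation;
* closed-form simulator checks at 10^4 replicates; oracle equivalence
  on 200 random toy tables; bootstrap coverage on a one-parameter
  two-population toy at 50 outer x 30 inner replicates.

## Known limitations

* At 2,000 SNPs the composite likelihood is nearly flat along the
  (T_1, PW-WGB migration, N_WGB) and (T_3, WAS-EGB migration) ridges:
  high-precision conditional slices at the generating values show only
  ~2-40 lnCL units of curvature across a nine-fold parameter range for
  m_pw, m_wp and N_WGB, against a seed-to-seed evaluation noise of
  ~5-15 units. Recovery of those parameters at reduced scale is
  therefore fragile even with a converged optimiser; the divergence
  times T_3 and the sizes N_WAS, N_EGB are strongly identified. At the
  full 20,000-SNP scale the curvature grows ten-fold and the ridges
  resolve.
* The synthetic generator emulates GBS structure (short loci, one
  retained SNP per locus, independent missingness, locality grouping)
  but not allele dropout correlated with genotype, depth-dependent
  errors, paralog collapse, or within-locus linkage; passing tests
  demonstrate correctness of the estimators and machinery, not
  robustness to those artefacts.
* Migration is piecewise constant and pairwise between adjacent extant
  populations; no growth within epochs, no gene flow involving
  ancestral demes.
* The likelihood treats SNPs as independent (composite); bootstrap
  intervals, not curvature-based standard errors, quantify uncertainty.
* A weakly converged fit can push every merge time beyond the
  genealogical horizon that migration sustains; no merge is then ever
  reached, the three topologies describe the same process, and their
  AICs tie exactly. Reduced-scale model selection therefore depends on
  fit convergence as much as on the data.
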