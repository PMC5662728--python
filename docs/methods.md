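# Methods

## The assignment model

`gsikit` assigns diploid multilocus genotypes to candidate source populations
with the Rannala–Mountain conditional likelihood. The baseline allele counts
of each population are treated as known data; the unknown population allele
frequencies carry a symmetric Dirichlet prior with mass 1/k per allele class,
where k is the number of distinct alleles observed at the locus across the
*union* of baseline and query registries. Integrating the frequencies out
gives a Dirichlet-multinomial predictive for a two-allele draw:

    P(aa | counts) = (n_a + 1/k)(n_a + 1 + 1/k) / ((n + 1)(n + 2))
    P(ab | counts) = 2 (n_a + 1/k)(n_b + 1/k) / ((n + 1)(n + 2))

with n_a the count of allele a and n the scored gene copies at the locus.
Loci are treated as independent: log-likelihoods are summed, so the
computation cannot underflow even for many loci and large registries.
A missing locus contributes a factor of one. Posteriors use equal priors
over baseline populations; reporting-group posteriors are sums over member
populations, which makes the implied group prior proportional to the number
of populations in the group (an equal-group-prior variant would rescale
before normalizing; the population-level default matches the convention of
the standard GSI tools).

Key design choices:

- **k is the union-registry allele count, constant across populations.** The
  prior must put mass on query alleles absent from a particular reference
  population, otherwise a single novel allele would zero out the likelihood.
  Mixture files are merged into the registry at dataset assembly
  (`assemble_dataset(..., extra_loci=...)`), so mixture-only alleles get
  zero baseline counts rather than crashing.
- **Leave-one-out jackknife.** For self-assignment each baseline fish's own
  two alleles are subtracted from its home population's counts (per scored
  locus) before computing its likelihood there. This is algebraically
  identical to removing the fish from the file and re-assigning it; the test
  suite verifies the identity to 1e-12.
- **Ties** in the maximum a posteriori population break to the lowest
  population index and are flagged, keeping runs deterministic.
- **Individuals with zero scored loci** keep a uniform (prior-only) posterior
  row, are flagged unassignable, and are excluded from mixture estimation
  with a recorded count.

## Mixture estimation

Two estimators of the proportional contribution vector π are provided:

- **mean-posterior** (default): the average of the equal-prior posteriors
  across individuals — the conventional first approximation of ancestral
  contribution.
- **em**: conditional maximum likelihood via EM, iterating
  π_u ← (1/M) Σ_i π_u L_iu / Σ_v π_v L_iv from a uniform start until the
  largest change falls below `tol` (default 1e-6, `max_iter` 10000). The
  observed-data log-likelihood is checked to be non-decreasing at every
  step. Because the update only uses likelihood *ratios* within an
  individual, the EM operates directly on equal-prior posterior rows.

Head counts per unit are maximum a posteriori under the method's final
priors, mirroring the "number of individuals allocated" presentation of
mixture figures. The major-contributor flag defaults to a 10% contribution
threshold, the conventional cutoff for treating a lineage as a putative
donor.

## Population-genetic statistics

- **Expected heterozygosity** is unbiased gene diversity per locus,
  (2n/(2n−1))(1 − Σ p̂²), averaged over loci; the plain (biased) estimator is
  available via `unbiased=False`. Which variant a given published table used
  is often unstated, so both are exposed.
- **Allelic richness** uses hypergeometric rarefaction to g gene copies:
  AR(g) = Σ_a [1 − C(N−N_a, g)/C(N, g)]. g is expressed in gene copies; the
  conventional "minimum sample size of 12 individuals" is g = 24. When
  missing data push a locus's total below g, that locus is rarefied at its
  own total (recorded in the `g_used` column) rather than dropped.
- **Weir–Cockerham θ and f** are computed from per-locus, per-allele variance
  components a (among populations), b (among individuals within populations)
  and c (within individuals), pooled over alleles and loci *before* the
  ratios (ratio of sums, not mean of ratios — the multilocus convention of
  the cited estimator). Per locus, only populations with at least one scored
  individual enter. A dataset monomorphic at every locus yields a flagged
  undefined estimate, not a crash. The single-population specialisation
  (r = 1) provides the multilocus f used by the heterozygote-deficit test.
- **Permutation tests** replace the classical Markov-chain exact tests with
  deterministic, seeded permutation schemes:
  - *genic differentiation*: G statistic of the 2×k allele-count table summed
    over loci; the null permutes whole multilocus genotypes between the two
    collections (preserving within-individual structure);
  - *heterozygote deficit*: statistic is multilocus f, one-sided for f > 0
    (the direction of interest when pooling could mask substructure — the
    Wahlund effect); the null re-pairs alleles at random among scored
    individuals within each locus;
  - *composite linkage disequilibrium*: G of the two-locus genotype
    contingency table, permuting one locus's genotype column.
  All p-values are computed as (1 + #{perm ≥ obs})/(n_perm + 1), so they lie
  in (0, 1]; monomorphic inputs return p = 1 with a flag. Null calibration
  is verified distributionally (KS test against Uniform(0,1) over 200
  replicates).
- Locus-level neutrality screening (F_ST-outlier scans) is intentionally not
  implemented; analyses that must drop candidate-selection loci do so via
  config-driven exclusion lists, applied to the population-genetic stages
  only — assignment retains all loci, since mixture analysis is robust to
  modest departures from neutrality.

## The synthetic baseline generator

The generator is a two-level Balding–Nichols hierarchy. Per locus, ancestral
frequencies are symmetric Dirichlet(1) over the allele classes; each
reporting group draws its frequencies from Dirichlet(p_anc (1−F_b)/F_b), and
each population within a group from Dirichlet(p_group (1−F_w)/F_w).
Genotypes are drawn at Hardy–Weinberg equilibrium with independent loci.
F = 0 is accepted as an exact no-extra-divergence shortcut (used for
single-level designs such as calibration baselines). Defaults — 5 groups × 2
populations, 13 loci, 10 alleles per locus, 50 diploids per population,
F_between = 0.05, F_within = 0.01 — emulate a compact microsatellite
baseline with differentiation in the empirical range of coast-wide salmon
baselines (overall F_ST a few to several percent, sister lineages an order
of magnitude closer).

The registry of the emitted dataset contains observed alleles only, as real
compiled baselines do; the true frequency tables are returned separately on
the full allele label set so estimator tests can separate sampling noise
from bias. Mixtures contain pure-origin individuals (two alleles per locus
from one population's true frequencies) and F1 admixed individuals (one
allele per locus from each parent population), with per-individual truth
tags. `inject_missing` blanks individual×locus entries independently; at 13
loci a rate of 1/13 reproduces the "average 12 of 13 loci scored" regime of
typical microsatellite datasets.

What the generator does *not* emulate: stepwise microsatellite mutation,
linkage, allele-size homoplasy, genotyping artifacts (large-allele dropout,
stutter), or multi-generation drift after founding. Tests passing on this
generator therefore demonstrate correctness of the estimators and the
assignment machinery under the stated model, not robustness to those
real-data complications.

## The mixed-origin founding simulation

The simulation asks how assignment treats genotypes from a population founded
by two sources. The admixed population is ideal — one generation at
equilibrium, frequencies the unweighted arithmetic mean of the two sources'
maximum-likelihood frequency estimates (the "large and equal founder
numbers" idealization; a pooled-count variant is exposed via
`pooled_frequencies=True`, the two differing only when source sample sizes
differ). Sampled fish are assigned against the full baseline, aggregated to
reporting groups, and categorized by maximum a posteriori group as true
(either source's group), sister (declared sisters of the source groups —
sister relations are user input via the hierarchy's tag column, never
inferred), or unrelated. Among unrelated-assigned fish the share with max
posterior ≥ 0.8 is reported: these are confident-looking but spurious
assignments. Pure-origin control cohorts of the same size from each source's
own frequencies are always run alongside as the ordinary-misassignment
baseline.

The packaged *sister scenario* (`generate_sister_scenario`) provides the
structure this experiment needs with known truth: two truth groups, each
with one sister group at low divergence (lineages diverge from the ancestral
pool at F = 0.075, within a truth/sister pair at F = 0.0075, so pairwise
sister θ ≈ 0.015), plus 40 unrelated groups at F = 0.075, one population of
150 diploids per group, 12 loci × 12 alleles. On this scenario admixed fish
assign to unrelated groups at an order of magnitude above the pure-control
rate, and a substantial share of those spurious assignments carry P ≥ 0.8 —
the qualitative phenomenon the simulation exists to expose. The exact
fractions depend on the divergence geometry of the baseline, so they are
reported, not asserted against any fixed value; the test suite asserts the
ratio (≥ 3× over 10 seeds) and the existence of high-confidence spurious
assignments.

## Pipeline and reproducibility

`run_study` executes load → pool → diversity/F-statistics/differentiation
tests (popgen exclusions applied) → leave-one-out self-assignment → mixture
assignment, group aggregation, estimation and the major-contributor table
(assignment exclusions applied; by default none) → optional founding
simulation. A single global seed spawns per-stage substreams via
`numpy.random.SeedSequence`, so stages are individually reproducible and a
rerun with the same configuration is bitwise identical. Every TSV artifact
carries a header comment with the configuration hash and seed; unassignable
individuals and locus exclusions are logged. Any stage failure aborts with a
stage-named error.

## Problem sizes used in validation

The validation suite (`tests/test_acceptance.py`, `scripts/acceptance.py`)
uses: exhaustive oracle comparison over all count vectors with entries ≤ 10
and k ≤ 3; 100 fish for the leave-one-out identity; 10 seeds × 200 fish ×
12 loci for EM recovery of π = (0.7, 0.3) at source divergence F ≈ 0.05;
20 seeds × 5 populations × 100 diploids × 15 loci for θ calibration at
F ∈ {0.01, 0.05, 0.1} and for f under HWE; 200 replicates × 199 permutations
for null uniformity; and 10 seeds × 1000 admixed fish (plus 2 × 1000
controls) for the sister scenario. These sizes give Monte-Carlo error
comfortably below the asserted tolerances while keeping the full validation
run under a minute on a single core.

## Known limitations

- Individual assignment assumes every query originates from one baseline
  population; the founding simulation quantifies exactly how that assumption
  fails for admixed genotypes, but no admixture-aware estimator (model-based
  clustering) is included.
- The EM mixture estimator conditions on baseline frequencies as known
  (no baseline resampling), so its uncertainty is understated for small
  reference samples.
- Permutation tests are approximations to exact tests; at very small samples
  the discreteness of the permutation distribution makes them conservative.
- GENEPOP parsing accepts the common dialect (individuals as line records,
  locus names one-per-line or comma-separated); exotic variants are not
  supported.
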