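# gsikit

Genetic stock identification (GSI) for microsatellite data: who founded an
introduced population, and how much does each donor lineage contribute?

`gsikit` is aimed at population geneticists working with mixed-stock or
introduced populations — the canonical case being Pacific salmon, where
coast-wide reference baselines of known-origin populations (nested within
reporting groups, or lineages) are compared against samples of unknown
origin. It provides:

- **GENEPOP I/O** for diploid multilocus genotypes, plus a
  population-to-reporting-group hierarchy table with optional sister-group
  tags, and registry merging so mixture-only alleles never crash assignment.
- **Population-genetic summaries**: unbiased expected heterozygosity
  *H*<sub>S</sub>, allelic richness *AR* rarefied to a fixed number of gene
  copies, Weir–Cockerham *θ* (F<sub>ST</sub>) and *f* (F<sub>IS</sub>) from
  pooled variance components, pairwise *θ* matrices, permutation tests for
  genic differentiation, heterozygote deficit and composite linkage
  disequilibrium, and Bonferroni correction.
- **Individual assignment** with the Rannala–Mountain conditional
  likelihood. With *n<sub>a</sub>* copies of allele *a* among *n* scored gene
  copies in a candidate population and *k* allele classes at the locus, the
  genotype likelihood is

  P(aa) = (n<sub>a</sub> + 1/k)(n<sub>a</sub> + 1 + 1/k) / ((n + 1)(n + 2)),
  P(ab) = 2(n<sub>a</sub> + 1/k)(n<sub>b</sub> + 1/k) / ((n + 1)(n + 2)),

  multiplied across loci; posteriors use equal population priors and are
  aggregated to reporting groups. A leave-one-out jackknife self-assignment
  benchmarks baseline resolving power.
- **Mixture-proportion estimation** as the mean posterior across individuals
  or by EM conditional maximum likelihood
  (π<sub>u</sub> ← (1/M) Σ<sub>i</sub> π<sub>u</sub>L<sub>iu</sub> / Σ<sub>v</sub> π<sub>v</sub>L<sub>iv</sub>),
  with max-a-posteriori head counts and a 10%-contribution "major
  contributor" flag.
- **A mixed-origin founding simulation**: build an ideal admixed population
  with frequencies intermediate between two baseline sources, draw genotypes
  at Hardy–Weinberg equilibrium, assign them, and tabulate the fractions
  assigned to the true groups, to declared sister groups, and — the
  diagnostic of interest — to unrelated groups, including the share of those
  spurious assignments carrying high confidence (P ≥ 0.8). Pure-origin
  control cohorts quantify the ordinary misassignment baseline.
- **A synthetic baseline generator** (Balding–Nichols Dirichlet hierarchy)
  so every stage is testable with known truth and no external data.

## Worked example

Generate a hierarchical baseline (4 reporting groups × 2 populations,
13 loci), a 150-fish mixture drawn 60% from `G01_P1`, 30% from `G03_P2` and
10% F1 crosses of the two, then assign and estimate composition:

```python
from gsikit.synthetic import SyntheticBaselineSpec, generate_baseline, generate_mixture
from gsikit.io import assemble_dataset, remap_collection
from gsikit.assignment import (assignment_posteriors, estimate_mixture,
                               report_major_contributors, self_assignment_confusion)

spec = SyntheticBaselineSpec(n_groups=4, pops_per_group=2, f_between=0.06,
                             f_within=0.01, n_loci=13, alleles_per_locus=10,
                             n_per_pop=60, seed=42)
baseline, truth = generate_baseline(spec)
mix, tags = generate_mixture(truth, {"G01_P1": 0.6, "G03_P2": 0.3}, n=150,
                             f1_pairs_with_rates={("G01_P1", "G03_P2"): 0.1}, seed=7)
baseline = assemble_dataset(baseline.collections, baseline.hierarchy,
                            extra_loci=[mix.loci])
mix = remap_collection(mix, baseline.loci)

conf = self_assignment_confusion(baseline, level="group")
print(f"baseline self-assignment accuracy (group level): {conf.accuracy:.3f}")
pm = assignment_posteriors(mix, baseline)
est = estimate_mixture(pm, method="em", hierarchy=baseline.hierarchy, level="group")
print(report_major_contributors(est, threshold=0.10).to_string(index=False,
                                                               float_format="%.4f"))
```

Output:

```
baseline self-assignment accuracy (group level): 0.979
unit  proportion  count  major
 G01      0.6553     97   True
 G03      0.3377     52   True
 G04      0.0070      1  False
 G02      0.0000      0  False
```

The EM estimate recovers the true 0.6 / 0.3 composition (the F1 fish split
their posterior between their two parent lineages, inflating both), the head
counts are the number of fish allocated to each lineage by maximum a
posteriori probability, and only the two real donors clear the 10%
major-contributor threshold.

The same workflow is scriptable from a shell — `gsikit simulate-baseline`,
`summarize`, `self-assign`, `assign`, `mixture`, `founding-sim`, and
`run-all --config config.yaml` for the end-to-end study bundle; see
`gsikit --help`.

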