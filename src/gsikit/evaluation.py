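"""Benchmark routines: estimator calibration, oracle agreement, and the
sister-scenario misassignment study.

These functions re-run the package's own methods on synthetic data with known
truth and return the summary quantities a validation report needs. The
Dirichlet-multinomial oracle here is computed by explicit sequential urn
enumeration, independent of the closed-form likelihood in
:mod:`gsikit.assignment`.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats

from .assignment import (
    assignment_posteriors,
    estimate_mixture,
    rm_genotype_probability,
)
from .founding import FoundingSpec, run_founding_simulation
from .io import BaselineDataset, pool_collections, remap_collection
from .popgen import fis_estimate, genic_differentiation_test, weir_cockerham
from .synthetic import (
    SyntheticBaselineSpec,
    generate_baseline,
    generate_mixture,
    generate_sister_scenario,
)

__all__ = [
    "dirichlet_predictive_by_enumeration",
    "rm_oracle_max_error",
    "loo_identity_max_error",
    "em_recovery_error",
    "theta_calibration",
    "fis_null_mean",
    "null_pvalue_uniformity",
    "sister_scenario_study",
]


def dirichlet_predictive_by_enumeration(
    genotype: tuple[int, int], counts, k: int
) -> float:
    """Genotype probability by enumerating ordered two-allele urn draws.

    Each allele class carries prior mass 1/k; after observing the baseline
    counts, successive draws follow the Polya urn: the first allele is drawn
    with probability (n_a + 1/k)/(n + 1), then the counts are updated and the
    second drawn the same way. Summing the ordered sequences consistent with
    the unordered genotype gives the predictive probability. This is the
    brute-force oracle for the closed-form likelihood.
    """
    counts = [float(c) for c in counts]
    n = sum(counts)
    a, b = genotype
    total = 0.0
    orders = {(a, b), (b, a)}
    for first, second in orders:
        urn = list(counts)
        p1 = (urn[first] + 1.0 / k) / (n + 1.0)
        urn[first] += 1.0
        p2 = (urn[second] + 1.0 / k) / (n + 2.0)
        total += p1 * p2
    return total


def rm_oracle_max_error(max_count: int = 10, max_k: int = 3) -> tuple[float, int]:
    """Max |closed form - urn enumeration| over all count vectors with entries
    up to ``max_count`` and registries up to ``max_k`` classes; returns
    (max error, number of cases checked)."""
    worst = 0.0
    n_cases = 0
    for k in range(1, max_k + 1):
        for counts in itertools.product(range(max_count + 1), repeat=k):
            arr = np.array(counts, dtype=float)
            for a in range(k):
                for b in range(a, k):
                    closed = rm_genotype_probability((a, b), arr, k)
                    oracle = dirichlet_predictive_by_enumeration((a, b), counts, k)
                    worst = max(worst, abs(closed - oracle))
                    n_cases += 1
    return worst, n_cases


def loo_identity_max_error(seed: int = 0, n_checked: int = 100) -> tuple[float, int]:
    """Leave-one-out flag vs physically removing the fish and re-assigning.

    Removes each sampled baseline individual from its collection, rebuilds the
    baseline, assigns the fish, and compares the posterior row with the
    loo-flagged assignment from the intact baseline. Returns (max abs
    difference, individuals checked).
    """
    from .io import GenotypeCollection

    spec = SyntheticBaselineSpec(
        n_groups=3, pops_per_group=2, n_loci=10, alleles_per_locus=8,
        n_per_pop=30, missing_rate=0.05, seed=seed,
    )
    dataset, _ = generate_baseline(spec)
    queries = pool_collections(dataset.collections, "self")
    home = [c.id for c in dataset.collections for _ in c.individual_ids]
    pm = assignment_posteriors(queries, dataset, leave_one_out=True, home_pops=home)

    rng = np.random.default_rng(seed + 1)
    picks = rng.choice(queries.n_individuals, size=n_checked, replace=True)
    sizes = np.cumsum([0] + [c.n_individuals for c in dataset.collections])
    worst = 0.0
    for gi in picks:
        ci = int(np.searchsorted(sizes, gi, side="right") - 1)
        li = int(gi - sizes[ci])
        colls = []
        for j, c in enumerate(dataset.collections):
            if j != ci:
                colls.append(c)
                continue
            keep = [i for i in range(c.n_individuals) if i != li]
            colls.append(
                GenotypeCollection(
                    id=c.id,
                    individual_ids=[c.individual_ids[i] for i in keep],
                    loci=c.loci,
                    calls=c.calls[keep],
                )
            )
        reduced = BaselineDataset(
            collections=colls, hierarchy=dataset.hierarchy, loci=dataset.loci
        )
        one = GenotypeCollection(
            id="one",
            individual_ids=[queries.individual_ids[gi]],
            loci=dataset.loci,
            calls=queries.calls[[gi]],
        )
        pm_one = assignment_posteriors(one, reduced)
        worst = max(worst, float(np.max(np.abs(pm_one.q[0] - pm.q[gi]))))
    return worst, n_checked


def _two_pop_mixture(seed: int, pi=(0.7, 0.3), n_mix=200, n_base=200,
                     n_loci=12, alleles=10, f=0.05):
    """Generate a two-population baseline plus a mixture with known proportions,
    remapped onto the union registry; returns (dataset, mixture collection)."""
    spec = SyntheticBaselineSpec(
        n_groups=2, pops_per_group=1, f_between=f, f_within=0.0,
        n_loci=n_loci, alleles_per_locus=alleles, n_per_pop=n_base, seed=seed,
    )
    dataset, truth = generate_baseline(spec)
    pops = dataset.pop_ids
    mix, _ = generate_mixture(
        truth, {pops[0]: pi[0], pops[1]: pi[1]}, n=n_mix, seed=seed + 7,
    )
    from .io import assemble_dataset

    dataset = assemble_dataset(
        dataset.collections, dataset.hierarchy, extra_loci=[mix.loci]
    )
    mix = remap_collection(mix, dataset.loci)
    return dataset, mix


def em_recovery_error(
    seeds, pi=(0.7, 0.3), n_mix: int = 200, n_loci: int = 12
) -> float:
    """Mean (over seeds) max-norm error of the EM mixture estimate."""
    errs = []
    for s in seeds:
        dataset, mix = _two_pop_mixture(int(s), pi=pi, n_mix=n_mix, n_loci=n_loci)
        pm = assignment_posteriors(mix, dataset)
        est = estimate_mixture(pm, method="em")
        errs.append(float(np.max(np.abs(est.proportions - np.array(pi)))))
    return float(np.mean(errs))


def theta_calibration(F: float, seeds, n_per_pop: int = 100) -> float:
    """Mean multilocus theta over seeded Balding–Nichols baselines at ``F``
    (5 populations, 15 loci, 8 alleles)."""
    thetas = []
    for s in seeds:
        spec = SyntheticBaselineSpec(
            n_groups=5, pops_per_group=1, f_between=F, f_within=0.0,
            n_loci=15, alleles_per_locus=8, n_per_pop=n_per_pop, seed=int(s),
        )
        dataset, _ = generate_baseline(spec)
        thetas.append(weir_cockerham(dataset.collections).theta)
    return float(np.mean(thetas))


def fis_null_mean(seeds, n_per_pop: int = 100) -> float:
    """Mean multilocus f over HWE-sampled single populations."""
    vals = []
    for s in seeds:
        spec = SyntheticBaselineSpec(
            n_groups=1, pops_per_group=1, f_between=0.0, f_within=0.0,
            n_loci=15, alleles_per_locus=8, n_per_pop=n_per_pop, seed=int(s),
        )
        dataset, _ = generate_baseline(spec)
        vals.append(fis_estimate(dataset.collections[0]))
    return float(np.mean(vals))


def null_pvalue_uniformity(
    seed: int = 0, n_replicates: int = 200, n_perm: int = 199, n_per_coll: int = 30
) -> tuple[float, np.ndarray]:
    """KS p-value (vs Uniform(0,1)) of genic-test p-values under the null.

    Each replicate draws two collections from the same population frequencies
    and runs the genotype-permutation G test. Returns (KS p-value, p-values).
    """
    pvals = []
    root = np.random.SeedSequence(seed)
    for i, child in enumerate(root.spawn(n_replicates)):
        s = int(child.generate_state(1)[0] % (2**31))
        spec = SyntheticBaselineSpec(
            n_groups=1, pops_per_group=2, f_between=0.0, f_within=0.0,
            n_loci=10, alleles_per_locus=8, n_per_pop=n_per_coll, seed=s,
        )
        dataset, _ = generate_baseline(spec)
        res = genic_differentiation_test(
            dataset.collections[0], dataset.collections[1],
            n_perm=n_perm, seed=s + 1,
        )
        pvals.append(res.p_value)
    pvals = np.array(pvals)
    ks = stats.kstest(pvals, "uniform")
    return float(ks.pvalue), pvals


def sister_scenario_study(seeds, n_fish: int = 1000, n_per_pop: int = 150) -> dict:
    """Run the mixed-origin founding simulation on the synthetic sister
    scenario over several seeds and summarize.

    Returns means over seeds of the admixed cohort's true/sister/unrelated
    fractions, the high-confidence unrelated share, the pooled pure-control
    unrelated rate, and the admixed:pure unrelated-misassignment ratio.
    """
    adm_true, adm_sis, adm_unrel, adm_hc, ctl_unrel = [], [], [], [], []
    hc_any = 0
    for s in seeds:
        dataset, _, sources, _ = generate_sister_scenario(
            seed=int(s), n_per_pop=n_per_pop
        )
        spec = FoundingSpec(
            source_pop_a=sources[0], source_pop_b=sources[1],
            n_individuals=n_fish, seed=int(s) + 101,
        )
        rep = run_founding_simulation(spec, dataset)
        adm_true.append(rep.admixed.fraction_true)
        adm_sis.append(rep.admixed.fraction_sister)
        adm_unrel.append(rep.admixed.fraction_unrelated)
        adm_hc.append(rep.admixed.fraction_unrelated_highconf)
        ctl_unrel.append(rep.controls.fraction_unrelated)
        hc_any += int(
            rep.admixed.fraction_unrelated_highconf > 0 and rep.admixed.n_unrelated > 0
        )
    mean_ctl = float(np.mean(ctl_unrel))
    mean_adm = float(np.mean(adm_unrel))
    return {
        "fraction_true": float(np.mean(adm_true)),
        "fraction_sister": float(np.mean(adm_sis)),
        "fraction_unrelated": mean_adm,
        "fraction_unrelated_highconf": float(np.mean(adm_hc)),
        "control_fraction_unrelated": mean_ctl,
        "admixed_to_pure_ratio": (mean_adm / mean_ctl) if mean_ctl > 0 else float("inf"),
        "seeds_with_highconf_unrelated": hc_any,
        "n_seeds": len(list(seeds)),
    }
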