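"""Synthetic hierarchical baselines and mixtures with known truth.

Population allele frequencies follow the Balding–Nichols construction:
ancestral frequencies per locus are symmetric Dirichlet(1); each reporting
group draws from Dirichlet(p_anc (1-F_b)/F_b); each population within a group
draws from Dirichlet(p_group (1-F_w)/F_w). F_b and F_w calibrate the
between-group and within-group differentiation (the Weir–Cockerham theta of
the sampled data tracks the generating F). Genotypes are sampled at
Hardy–Weinberg equilibrium with independent loci.

True frequency tables are emitted separately from the sampled data so that
estimator tests can separate sampling noise from bias. The emitted registry
contains observed alleles only, as in real compiled baselines; rare ancestral
alleles may therefore be absent from the registry while present in the truth
table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    MISSING,
    BaselineDataset,
    BaselineHierarchy,
    GenotypeCollection,
    Locus,
)

__all__ = [
    "SyntheticBaselineSpec",
    "TruthFrequencies",
    "generate_baseline",
    "generate_mixture",
    "inject_missing",
    "generate_sister_scenario",
]


@dataclass
class SyntheticBaselineSpec:
    """Parameters of a two-level (group / population) synthetic baseline.

    Defaults emulate a compact microsatellite baseline: 5 reporting groups of
    2 populations, 13 highly polymorphic loci, moderate between-group
    differentiation (F ~ 0.05, the empirical range of coast-wide salmon
    baselines) and weak within-group structure.
    """

    n_groups: int = 5
    pops_per_group: int = 2
    f_between: float = 0.05
    f_within: float = 0.01
    n_loci: int = 13
    alleles_per_locus: int | list[int] = 10
    n_per_pop: int = 50
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.f_between < 1) or not (0 <= self.f_within < 1):
            raise ValueError("F parameters must lie in [0, 1)")
        if self.n_groups < 1 or self.pops_per_group < 1 or self.n_per_pop < 1:
            raise ValueError("counts must be positive")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        ks = self.allele_counts()
        if min(ks) < 2:
            raise ValueError("alleles_per_locus must be >= 2")

    def allele_counts(self) -> list[int]:
        if isinstance(self.alleles_per_locus, int):
            return [self.alleles_per_locus] * self.n_loci
        if len(self.alleles_per_locus) != self.n_loci:
            raise ValueError("alleles_per_locus list must have n_loci entries")
        return list(self.alleles_per_locus)


@dataclass
class TruthFrequencies:
    """Generating allele frequencies per population, on the full allele label set."""

    pop_ids: list[str]
    locus_names: list[str]
    allele_labels: list[tuple[int, ...]]  # full label set per locus
    freqs: dict[str, list[np.ndarray]]  # pop -> per-locus frequency vectors

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pop in self.pop_ids:
            for l, name in enumerate(self.locus_names):
                for lab, f in zip(self.allele_labels[l], self.freqs[pop][l]):
                    rows.append((pop, name, lab, f))
        return pd.DataFrame(rows, columns=["population", "locus", "allele", "freq"])


def balding_nichols(p: np.ndarray, F: float, rng: np.random.Generator) -> np.ndarray:
    """Draw daughter frequencies around ``p`` with differentiation ``F``.

    ``F = 0`` returns ``p`` unchanged (exact no-divergence shortcut).
    """
    if F <= 0:
        return np.asarray(p, dtype=float).copy()
    alpha = np.maximum(np.asarray(p, dtype=float) * (1.0 - F) / F, 1e-12)
    return rng.dirichlet(alpha)


def _sample_calls(
    pop_freqs: list[np.ndarray], n: int, rng: np.random.Generator
) -> np.ndarray:
    """HWE genotypes in full-allele index space, shape (n, L, 2)."""
    L = len(pop_freqs)
    calls = np.empty((n, L, 2), dtype=np.int32)
    for l, f in enumerate(pop_freqs):
        draws = rng.choice(len(f), size=2 * n, p=f)
        calls[:, l, :] = draws.reshape(n, 2)
    return calls


def _allele_labels(ks: list[int]) -> list[tuple[int, ...]]:
    # microsatellite-style codes: 3-digit, distinct, ascending
    return [tuple(101 + 2 * j for j in range(k)) for k in ks]


def _compress_observed(
    calls_by_pop: dict[str, np.ndarray],
    locus_names: list[str],
    labels_full: list[tuple[int, ...]],
) -> tuple[list[Locus], dict[str, np.ndarray]]:
    """Build an observed-alleles-only registry and re-index all calls onto it."""
    L = len(locus_names)
    observed: list[np.ndarray] = []
    for l in range(L):
        vals = np.concatenate(
            [c[:, l, :].ravel() for c in calls_by_pop.values()]
        )
        vals = vals[vals != MISSING]
        observed.append(np.unique(vals))
    loci = [
        Locus(
            name=locus_names[l],
            alleles=tuple(labels_full[l][j] for j in observed[l]),
        )
        for l in range(L)
    ]
    remapped = {}
    for pop, calls in calls_by_pop.items():
        out = np.full_like(calls, MISSING)
        for l in range(L):
            table = np.full(len(labels_full[l]), -1, dtype=np.int32)
            table[observed[l]] = np.arange(len(observed[l]))
            for i in (0, 1):
                col = calls[:, l, i]
                ok = col != MISSING
                out[ok, l, i] = table[col[ok]]
        remapped[pop] = out
    return loci, remapped


def generate_baseline(
    spec: SyntheticBaselineSpec,
) -> tuple[BaselineDataset, TruthFrequencies]:
    """Generate a hierarchical baseline plus its true frequency tables."""
    rng = np.random.default_rng(spec.seed)
    ks = spec.allele_counts()
    labels = _allele_labels(ks)
    locus_names = [f"Loc{l + 1:02d}" for l in range(spec.n_loci)]

    anc = [rng.dirichlet(np.ones(k)) for k in ks]
    pop_freqs: dict[str, list[np.ndarray]] = {}
    pop_to_group: dict[str, str] = {}
    for g in range(spec.n_groups):
        gid = f"G{g + 1:02d}"
        gfreq = [balding_nichols(anc[l], spec.f_between, rng) for l in range(spec.n_loci)]
        for p in range(spec.pops_per_group):
            pid = f"{gid}_P{p + 1}"
            pop_freqs[pid] = [
                balding_nichols(gfreq[l], spec.f_within, rng)
                for l in range(spec.n_loci)
            ]
            pop_to_group[pid] = gid

    calls_by_pop = {
        pid: _sample_calls(pop_freqs[pid], spec.n_per_pop, rng)
        for pid in pop_freqs
    }
    if spec.missing_rate > 0:
        for pid, calls in calls_by_pop.items():
            mask = rng.random(calls.shape[:2]) < spec.missing_rate
            calls[mask] = MISSING

    loci, remapped = _compress_observed(calls_by_pop, locus_names, labels)
    collections = [
        GenotypeCollection(
            id=pid,
            individual_ids=[f"{pid}_{i + 1:04d}" for i in range(spec.n_per_pop)],
            loci=loci,
            calls=remapped[pid],
        )
        for pid in pop_freqs
    ]
    hierarchy = BaselineHierarchy(pop_to_group=pop_to_group)
    dataset = BaselineDataset(collections=collections, hierarchy=hierarchy, loci=loci)
    truth = TruthFrequencies(
        pop_ids=list(pop_freqs),
        locus_names=locus_names,
        allele_labels=labels,
        freqs=pop_freqs,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# Mixtures


def generate_mixture(
    truth: TruthFrequencies,
    proportions: dict[str, float],
    n: int,
    f1_pairs_with_rates: dict[tuple[str, str], float] | None = None,
    seed: int = 0,
    mixture_id: str = "mixture",
) -> tuple[GenotypeCollection, pd.DataFrame]:
    """Sample a mixture of pure-origin and F1-admixed individuals.

    ``proportions`` gives pure-origin rates per source population;
    ``f1_pairs_with_rates`` gives rates for F1 crosses (one allele per locus
    from each parent population's true frequencies). All rates must sum to 1.
    Returns the collection (with an observed-alleles registry of its own) and
    a truth table recording each individual's origin.
    """
    f1 = dict(f1_pairs_with_rates or {})
    total = sum(proportions.values()) + sum(f1.values())
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError("proportions (+ F1 rates) must sum to 1")
    for pop in list(proportions) + [p for pair in f1 for p in pair]:
        if pop not in truth.freqs:
            raise KeyError(f"unknown population {pop!r} in mixture spec")
    rng = np.random.default_rng(seed)
    components: list[tuple[str, tuple[str, ...]]] = [
        ("pure", (pop,)) for pop in proportions
    ] + [("f1", pair) for pair in f1]
    rates = np.array(list(proportions.values()) + list(f1.values()))
    which = rng.choice(len(components), size=n, p=rates / rates.sum())

    L = len(truth.locus_names)
    calls = np.empty((n, L, 2), dtype=np.int32)
    rows = []
    for i in range(n):
        kind, pops = components[which[i]]
        if kind == "pure":
            fr = truth.freqs[pops[0]]
            for l in range(L):
                calls[i, l, :] = rng.choice(len(fr[l]), size=2, p=fr[l])
            rows.append((f"{mixture_id}_{i + 1:04d}", "pure", pops[0], ""))
        else:
            fa, fb = truth.freqs[pops[0]], truth.freqs[pops[1]]
            for l in range(L):
                calls[i, l, 0] = rng.choice(len(fa[l]), p=fa[l])
                calls[i, l, 1] = rng.choice(len(fb[l]), p=fb[l])
            rows.append((f"{mixture_id}_{i + 1:04d}", "f1", pops[0], pops[1]))
    loci, remapped = _compress_observed(
        {mixture_id: calls}, truth.locus_names, truth.allele_labels
    )
    coll = GenotypeCollection(
        id=mixture_id,
        individual_ids=[r[0] for r in rows],
        loci=loci,
        calls=remapped[mixture_id],
    )
    truth_df = pd.DataFrame(
        rows, columns=["individual", "origin_class", "pop_a", "pop_b"]
    )
    return coll, truth_df


def inject_missing(
    coll: GenotypeCollection, rate: float, seed: int = 0
) -> GenotypeCollection:
    """Independently blank each individual x locus entry with probability ``rate``."""
    if not (0 <= rate < 1):
        raise ValueError("rate must be in [0, 1)")
    if rate == 0:
        return GenotypeCollection(
            id=coll.id,
            individual_ids=list(coll.individual_ids),
            loci=coll.loci,
            calls=coll.calls.copy(),
        )
    rng = np.random.default_rng(seed)
    calls = coll.calls.copy()
    mask = rng.random(calls.shape[:2]) < rate
    calls[mask] = MISSING
    return GenotypeCollection(
        id=coll.id,
        individual_ids=list(coll.individual_ids),
        loci=coll.loci,
        calls=calls,
    )


# ---------------------------------------------------------------------------
# The sister scenario: the structure behind the mixed-origin founding study


def generate_sister_scenario(
    n_unrelated: int = 40,
    f_unrelated: float = 0.075,
    f_sister: float = 0.0075,
    n_loci: int = 12,
    alleles_per_locus: int = 12,
    n_per_pop: int = 150,
    seed: int = 0,
) -> tuple[BaselineDataset, TruthFrequencies, tuple[str, str], tuple[str, str]]:
    """A baseline with two truth groups, each with one low-divergence sister
    group, plus ``n_unrelated`` unrelated groups, one population per group.

    Truth/sister lineages diverge from the ancestral pool at ``f_unrelated``;
    within each truth/sister pair the two groups diverge at ``f_sister``
    (pairwise theta ~ 2 * f_sister). Returns the dataset (sister relations in
    the hierarchy), the truth frequencies, the two source population ids and
    the two truth group ids.
    """
    rng = np.random.default_rng(seed)
    ks = [alleles_per_locus] * n_loci
    labels = _allele_labels(ks)
    locus_names = [f"Loc{l + 1:02d}" for l in range(n_loci)]
    anc = [rng.dirichlet(np.ones(k)) for k in ks]

    pop_freqs: dict[str, list[np.ndarray]] = {}
    pop_to_group: dict[str, str] = {}
    sisters: dict[str, frozenset[str]] = {}
    for t in (1, 2):
        lineage = [balding_nichols(anc[l], f_unrelated, rng) for l in range(n_loci)]
        tg, sg = f"T{t}", f"S{t}"
        for gid in (tg, sg):
            pid = f"{gid}_P1"
            pop_freqs[pid] = [
                balding_nichols(lineage[l], f_sister, rng) for l in range(n_loci)
            ]
            pop_to_group[pid] = gid
        sisters[tg] = frozenset({sg})
        sisters[sg] = frozenset({tg})
    for u in range(n_unrelated):
        gid = f"U{u + 1:02d}"
        pid = f"{gid}_P1"
        pop_freqs[pid] = [balding_nichols(anc[l], f_unrelated, rng) for l in range(n_loci)]
        pop_to_group[pid] = gid

    calls_by_pop = {
        pid: _sample_calls(pop_freqs[pid], n_per_pop, rng) for pid in pop_freqs
    }
    loci, remapped = _compress_observed(calls_by_pop, locus_names, labels)
    collections = [
        GenotypeCollection(
            id=pid,
            individual_ids=[f"{pid}_{i + 1:04d}" for i in range(n_per_pop)],
            loci=loci,
            calls=remapped[pid],
        )
        for pid in pop_freqs
    ]
    hierarchy = BaselineHierarchy(pop_to_group=pop_to_group, sisters=sisters)
    dataset = BaselineDataset(collections=collections, hierarchy=hierarchy, loci=loci)
    truth = TruthFrequencies(
        pop_ids=list(pop_freqs),
        locus_names=locus_names,
        allele_labels=labels,
        freqs=pop_freqs,
    )
    return dataset, truth, ("T1_P1", "T2_P1"), ("T1", "T2")
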