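"""Mixed-origin founding simulation.

Quantifies how individual assignment treats genotypes from an admixed
population: an ideal equilibrium population with allele frequencies
intermediate between two baseline sources is constructed, genotypes are drawn
from it at Hardy–Weinberg equilibrium, assigned against the full baseline,
aggregated to reporting groups, and each fish is categorized by its maximum a
posteriori group as *true* (either source's group), *sister* (a declared
sister of a source group), or *unrelated*. Among the unrelated-assigned fish
the fraction with high assignment confidence (max posterior at or above a
threshold, conventionally 0.8) is tabulated — these are the assignments that
would mislead a naive reading of a stock-identification analysis.

Pure-origin control cohorts of the same size are always simulated alongside
from each source's own frequencies, giving the misassignment baseline that a
leave-one-out jackknife provides for real baseline fish.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .io import BaselineDataset, GenotypeCollection, Locus
from .assignment import (
    PosteriorMatrix,
    aggregate_to_groups,
    assignment_posteriors,
)

__all__ = [
    "FoundingSpec",
    "SimulationReport",
    "FoundingReport",
    "build_admixed_frequencies",
    "sample_hwe_genotypes",
    "categorize_assignments",
    "run_founding_simulation",
]


@dataclass
class FoundingSpec:
    """Configuration of one mixed-origin founding simulation."""

    source_pop_a: str
    source_pop_b: str
    n_individuals: int = 1000
    p_threshold: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.source_pop_a == self.source_pop_b:
            raise ValueError("the two source populations must be distinct")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")


@dataclass
class SimulationReport:
    """Outcome of categorizing one assigned cohort."""

    label: str
    n: int
    fraction_true: float
    fraction_sister: float
    fraction_unrelated: float
    fraction_unrelated_highconf: float  # among unrelated-assigned fish only
    n_unrelated: int
    per_group_counts: dict[str, int]
    truth_groups: tuple[str, str] | tuple[str, ...]
    sister_groups: tuple[str, ...]
    p_threshold: float
    seed: int | None = None

    def __post_init__(self) -> None:
        s = self.fraction_true + self.fraction_sister + self.fraction_unrelated
        if abs(s - 1.0) > 1e-9:
            raise ValueError("category fractions must partition unity")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FoundingReport:
    """Admixed cohort outcome plus pure-origin controls and full provenance."""

    spec: FoundingSpec
    admixed: SimulationReport
    controls: SimulationReport  # both pure cohorts pooled
    control_a: SimulationReport
    control_b: SimulationReport

    def to_json(self, path=None) -> str:
        payload = {
            "spec": asdict(self.spec),
            "admixed": self.admixed.to_dict(),
            "controls": self.controls.to_dict(),
            "control_a": self.control_a.to_dict(),
            "control_b": self.control_b.to_dict(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def build_admixed_frequencies(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    totals_a: np.ndarray,
    totals_b: np.ndarray,
    pooled: bool = False,
) -> tuple[list[np.ndarray], list[int]]:
    """Per-locus allele frequencies of the ideal admixed population.

    Default is the unweighted arithmetic mean of the two sources'
    maximum-likelihood frequency estimates ("large and equal numbers" of
    founders from each); ``pooled=True`` instead pools the raw counts. Loci
    where either source has no scored copies are dropped (their indices are
    returned for bookkeeping).
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    if counts_a.shape != counts_b.shape:
        raise ValueError("sources do not share a locus/allele registry")
    L = counts_a.shape[0]
    freqs: list[np.ndarray] = []
    kept: list[int] = []
    for l in range(L):
        ta, tb = float(totals_a[l]), float(totals_b[l])
        if ta == 0 or tb == 0:
            continue
        if pooled:
            f = (counts_a[l] + counts_b[l]) / (ta + tb)
        else:
            f = 0.5 * (counts_a[l] / ta + counts_b[l] / tb)
        freqs.append(f)
        kept.append(l)
    if not kept:
        raise ValueError("no locus is scored in both sources")
    return freqs, kept


def sample_hwe_genotypes(
    freqs: list[np.ndarray],
    loci: list[Locus],
    n: int,
    seed: int = 0,
    collection_id: str = "simulated",
) -> GenotypeCollection:
    """Draw ``n`` diploid genotypes, two independent alleles per locus (HWE)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    L = len(freqs)
    if L != len(loci):
        raise ValueError("freqs and loci length mismatch")
    calls = np.empty((n, L, 2), dtype=np.int32)
    for l, f in enumerate(freqs):
        f = np.asarray(f, dtype=float)
        if abs(f.sum() - 1.0) > 1e-6:
            raise ValueError(f"frequencies at locus {loci[l].name!r} do not sum to 1")
        k = loci[l].k
        calls[:, l, :] = rng.choice(k, size=(n, 2), p=f[:k] / f[:k].sum())
    return GenotypeCollection(
        id=collection_id,
        individual_ids=[f"{collection_id}_{i + 1:04d}" for i in range(n)],
        loci=loci,
        calls=calls,
    )


def categorize_assignments(
    group_posteriors: PosteriorMatrix,
    truth_groups: tuple[str, ...],
    sister_map: dict[str, frozenset[str]] | None,
    p_threshold: float = 0.8,
    label: str = "cohort",
    seed: int | None = None,
) -> SimulationReport:
    """Categorize each fish by its maximum a posteriori reporting group."""
    units = group_posteriors.unit_ids
    for g in truth_groups:
        if g not in units:
            raise ValueError(f"truth group {g!r} absent from hierarchy")
    sister_map = sister_map or {}
    sisters: set[str] = set()
    for g in truth_groups:
        sisters |= set(sister_map.get(g, frozenset()))
    sisters -= set(truth_groups)

    assigned = group_posteriors.map_units
    probs = group_posteriors.map_prob
    n = len(assigned)
    n_true = n_sis = n_unrel = n_unrel_hc = 0
    per_group: dict[str, int] = {}
    for g, p in zip(assigned, probs):
        per_group[g] = per_group.get(g, 0) + 1
        if g in truth_groups:
            n_true += 1
        elif g in sisters:
            n_sis += 1
        else:
            n_unrel += 1
            if p >= p_threshold:
                n_unrel_hc += 1
    return SimulationReport(
        label=label,
        n=n,
        fraction_true=n_true / n,
        fraction_sister=n_sis / n,
        fraction_unrelated=n_unrel / n,
        fraction_unrelated_highconf=(n_unrel_hc / n_unrel) if n_unrel else 0.0,
        n_unrelated=n_unrel,
        per_group_counts=dict(sorted(per_group.items())),
        truth_groups=tuple(truth_groups),
        sister_groups=tuple(sorted(sisters)),
        p_threshold=p_threshold,
        seed=seed,
    )


def _assign_and_categorize(
    coll: GenotypeCollection,
    baseline: BaselineDataset,
    truth_groups: tuple[str, str],
    p_threshold: float,
    label: str,
    seed: int,
) -> SimulationReport:
    pm = assignment_posteriors(coll, baseline)
    gm = aggregate_to_groups(pm, baseline.hierarchy)
    return categorize_assignments(
        gm,
        truth_groups,
        baseline.hierarchy.sisters,
        p_threshold=p_threshold,
        label=label,
        seed=seed,
    )


def run_founding_simulation(
    spec: FoundingSpec,
    baseline: BaselineDataset,
    pooled_frequencies: bool = False,
) -> FoundingReport:
    """Full pipeline: admix sources, sample, assign, aggregate, categorize.

    The two source populations' reporting groups are the truth groups; their
    declared sisters (from the baseline hierarchy) are the sister category.
    Pure-origin control cohorts of the same size are simulated from each
    source's own estimated frequencies and categorized identically.
    """
    from .popgen import allele_counts

    for pid in (spec.source_pop_a, spec.source_pop_b):
        baseline.collection(pid)  # raises if absent
    tab = allele_counts(baseline.collections)
    ia = tab.pop_ids.index(spec.source_pop_a)
    ib = tab.pop_ids.index(spec.source_pop_b)
    truth_groups = (
        baseline.hierarchy.group_of(spec.source_pop_a),
        baseline.hierarchy.group_of(spec.source_pop_b),
    )

    admix_freqs, kept = build_admixed_frequencies(
        tab.counts[ia], tab.counts[ib], tab.totals[ia], tab.totals[ib],
        pooled=pooled_frequencies,
    )
    loci_kept = [baseline.loci[l] for l in kept]
    ss = np.random.SeedSequence(spec.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]

    def pure_freqs(idx: int) -> list[np.ndarray]:
        out = []
        for l in kept:
            f = tab.counts[idx, l] / tab.totals[idx, l]
            out.append(f)
        return out

    cohorts = {
        "admixed": sample_hwe_genotypes(
            admix_freqs, loci_kept, spec.n_individuals, seed=seeds[0],
            collection_id="admixed",
        ),
        "control_a": sample_hwe_genotypes(
            pure_freqs(ia), loci_kept, spec.n_individuals, seed=seeds[1],
            collection_id="pure_a",
        ),
        "control_b": sample_hwe_genotypes(
            pure_freqs(ib), loci_kept, spec.n_individuals, seed=seeds[2],
            collection_id="pure_b",
        ),
    }
    # if loci were dropped, restrict the baseline to the kept loci
    if len(kept) != len(baseline.loci):
        names = [loc.name for loc in loci_kept]
        baseline = BaselineDataset(
            collections=[c.subset_loci(names) for c in baseline.collections],
            hierarchy=baseline.hierarchy,
            loci=loci_kept,
        )
    reports = {
        name: _assign_and_categorize(
            coll, baseline, truth_groups, spec.p_threshold, name, spec.seed
        )
        for name, coll in cohorts.items()
    }
    # pooled pure controls
    na = reports["control_a"].n
    nb = reports["control_b"].n
    per_group: dict[str, int] = {}
    for r in (reports["control_a"], reports["control_b"]):
        for g, c in r.per_group_counts.items():
            per_group[g] = per_group.get(g, 0) + c
    n_unrel = reports["control_a"].n_unrelated + reports["control_b"].n_unrelated
    hc = (
        reports["control_a"].fraction_unrelated_highconf * reports["control_a"].n_unrelated
        + reports["control_b"].fraction_unrelated_highconf * reports["control_b"].n_unrelated
    )
    controls = SimulationReport(
        label="controls",
        n=na + nb,
        fraction_true=(reports["control_a"].fraction_true * na + reports["control_b"].fraction_true * nb) / (na + nb),
        fraction_sister=(reports["control_a"].fraction_sister * na + reports["control_b"].fraction_sister * nb) / (na + nb),
        fraction_unrelated=(reports["control_a"].fraction_unrelated * na + reports["control_b"].fraction_unrelated * nb) / (na + nb),
        fraction_unrelated_highconf=(hc / n_unrel) if n_unrel else 0.0,
        n_unrelated=n_unrel,
        per_group_counts=dict(sorted(per_group.items())),
        truth_groups=truth_groups,
        sister_groups=reports["admixed"].sister_groups,
        p_threshold=spec.p_threshold,
        seed=spec.seed,
    )
    return FoundingReport(
        spec=spec,
        admixed=reports["admixed"],
        controls=controls,
        control_a=reports["control_a"],
        control_b=reports["control_b"],
    )
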