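"""Individual assignment and mixture estimation against a baseline.

The genotype likelihood is the Rannala–Mountain Dirichlet-multinomial
predictive: with ``n_a`` gene copies of allele ``a`` among ``n`` scored copies
in a candidate population, and ``k`` allele classes at the locus (prior mass
1/k per class),

    P(aa) = (n_a + 1/k)(n_a + 1 + 1/k) / ((n + 1)(n + 2))
    P(ab) = 2 (n_a + 1/k)(n_b + 1/k) / ((n + 1)(n + 2))

multiplied across loci in log space; missing loci contribute a factor of 1.
Posterior membership uses equal population priors. Leave-one-out
self-assignment removes each baseline fish's own two alleles from its home
population's counts before scoring it — the jackknife benchmark of baseline
resolving power.

Mixture composition is estimated either as the mean posterior across
individuals (the "approximation of overall genetic ancestral contribution")
or by EM conditional maximum likelihood, iterating
``pi_u <- (1/M) sum_i pi_u L_iu / sum_v pi_v L_iv`` from a uniform start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, BaselineDataset, BaselineHierarchy, GenotypeCollection

__all__ = [
    "PosteriorMatrix",
    "MixtureEstimate",
    "ConfusionMatrix",
    "rm_genotype_probability",
    "baseline_allele_counts",
    "assignment_posteriors",
    "aggregate_to_groups",
    "self_assignment_confusion",
    "estimate_mixture",
    "report_major_contributors",
]


@dataclass
class PosteriorMatrix:
    """Per-individual membership probabilities over baseline units.

    Rows sum to one. ``map_index``/``map_prob`` give the maximum a posteriori
    unit per individual (ties broken to the lowest unit index and flagged);
    individuals with zero scored loci keep a uniform (prior-only) row and are
    flagged unassignable.
    """

    individual_ids: list[str]
    unit_ids: list[str]
    q: np.ndarray  # (n, U)
    n_scored: np.ndarray  # (n,)
    level: str = "population"  # or "group"

    map_index: np.ndarray = field(init=False)
    map_prob: np.ndarray = field(init=False)
    tie: np.ndarray = field(init=False)
    unassignable: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if not np.allclose(self.q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("posterior rows must sum to 1")
        self.map_index = self.q.argmax(axis=1)
        self.map_prob = self.q[np.arange(len(self.q)), self.map_index]
        self.tie = (self.q == self.map_prob[:, None]).sum(axis=1) > 1
        self.unassignable = self.n_scored == 0

    @property
    def map_units(self) -> list[str]:
        return [self.unit_ids[i] for i in self.map_index]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.q, index=self.individual_ids, columns=self.unit_ids)
        df.insert(0, "n_scored", self.n_scored)
        df["map_unit"] = self.map_units
        df["map_prob"] = self.map_prob
        return df


@dataclass
class MixtureEstimate:
    """Proportional contribution per unit plus max-a-posteriori head counts."""

    unit_ids: list[str]
    proportions: np.ndarray
    counts: np.ndarray
    method: str  # "mean-posterior" | "em"
    level: str
    n_individuals: int
    n_excluded: int = 0
    n_iter: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if not np.isclose(self.proportions.sum(), 1.0, atol=1e-9):
            raise ValueError("mixture proportions must sum to 1")
        if int(self.counts.sum()) != self.n_individuals:
            raise ValueError("MAP counts must sum to the number of individuals")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit": self.unit_ids,
                "proportion": self.proportions,
                "count": self.counts,
            }
        )


@dataclass
class ConfusionMatrix:
    """True unit x assigned unit counts from leave-one-out self-assignment."""

    counts: pd.DataFrame

    @property
    def rates(self) -> pd.DataFrame:
        return self.counts.div(self.counts.sum(axis=1), axis=0)

    @property
    def accuracy(self) -> float:
        total = self.counts.to_numpy().sum()
        diag = sum(
            self.counts.at[u, u]
            for u in self.counts.index
            if u in self.counts.columns
        )
        return diag / total if total else float("nan")


# ---------------------------------------------------------------------------
# Rannala-Mountain likelihood


def rm_genotype_probability(
    genotype: tuple[int, int], counts: np.ndarray, k: int
) -> float:
    """Likelihood of one diploid genotype at one locus given baseline counts.

    ``genotype`` holds allele indices; ``counts`` the population's gene-copy
    counts over the registry; ``k`` the allele-class count of the prior.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    a, b = genotype
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    ik = 1.0 / k
    denom = (n + 1.0) * (n + 2.0)
    if a == b:
        return float((counts[a] + ik) * (counts[a] + 1.0 + ik) / denom)
    return float(2.0 * (counts[a] + ik) * (counts[b] + ik) / denom)


def baseline_allele_counts(
    baseline: BaselineDataset,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(counts (P,L,Amax), totals (P,L), k (L,)) over the shared registry."""
    from .popgen import allele_counts

    tab = allele_counts(baseline.collections)
    k = np.array([loc.k for loc in baseline.loci], dtype=np.int64)
    return tab.counts.astype(float), tab.totals.astype(float), k


def _log_likelihood_matrix(
    queries: GenotypeCollection,
    counts: np.ndarray,
    totals: np.ndarray,
    k: np.ndarray,
    home_pops: np.ndarray | None = None,
) -> np.ndarray:
    """(n, P) log-likelihoods; if ``home_pops`` given, each query's own two
    alleles are first removed from its home population's counts (leave-one-out)."""
    n, L = queries.n_individuals, queries.n_loci
    P = counts.shape[0]
    ll = np.zeros((n, P))
    for l in range(L):
        a = queries.calls[:, l, 0]
        b = queries.calls[:, l, 1]
        scored = a != MISSING
        if not scored.any():
            continue
        ai, bi = a[scored], b[scored]
        ik = 1.0 / k[l]
        na = counts[:, l, :][:, ai]  # (P, m)
        nb = counts[:, l, :][:, bi]
        ntot = totals[:, l][:, None]  # (P, 1)
        hom = (ai == bi)[None, :]
        num = np.where(
            hom,
            np.log(na + ik) + np.log(na + 1.0 + ik),
            np.log(2.0) + np.log(na + ik) + np.log(nb + ik),
        )
        term = num - np.log(ntot + 1.0) - np.log(ntot + 2.0)  # (P, m)
        rows = np.nonzero(scored)[0]
        ll[rows, :] += term.T

        if home_pops is not None:
            hp = home_pops[scored]
            na_h = counts[hp, l, ai]
            nb_h = counts[hp, l, bi]
            nt_h = totals[hp, l]
            hom1 = ai == bi
            na_new = np.where(hom1, na_h - 2.0, na_h - 1.0)
            nb_new = nb_h - 1.0
            if np.any(na_new < 0) or np.any(~hom1 & (nb_new < 0)) or np.any(nt_h < 2):
                raise ValueError(
                    "leave-one-out requested for alleles not present in baseline counts"
                )
            old = np.where(
                hom1,
                np.log(na_h + ik) + np.log(na_h + 1.0 + ik),
                np.log(2.0) + np.log(na_h + ik) + np.log(nb_h + ik),
            ) - np.log(nt_h + 1.0) - np.log(nt_h + 2.0)
            new = np.where(
                hom1,
                np.log(na_new + ik) + np.log(na_new + 1.0 + ik),
                np.log(2.0) + np.log(na_new + ik) + np.log(nb_new + ik),
            ) - np.log(nt_h - 1.0) - np.log(nt_h)
            ll[rows, hp] += new - old
    return ll


def assignment_posteriors(
    queries: GenotypeCollection,
    baseline: BaselineDataset,
    leave_one_out: bool = False,
    home_pops: list[str] | np.ndarray | None = None,
) -> PosteriorMatrix:
    """Posterior membership of each query over baseline populations.

    Equal priors across populations. With ``leave_one_out=True`` the queries
    must be baseline members and ``home_pops`` names each one's population.
    """
    if not baseline.collections:
        raise ValueError("empty baseline")
    if queries.loci != baseline.loci:
        raise ValueError(
            "queries and baseline must share a locus registry "
            "(use io.assemble_dataset with extra_loci, then io.remap_collection)"
        )
    counts, totals, k = baseline_allele_counts(baseline)
    hp_idx = None
    if leave_one_out:
        if home_pops is None:
            raise ValueError("leave_one_out requires home_pops")
        pos = {pid: i for i, pid in enumerate(baseline.pop_ids)}
        hp_idx = np.array([pos[p] for p in home_pops], dtype=np.int64)
    ll = _log_likelihood_matrix(queries, counts, totals, k, home_pops=hp_idx)
    ll -= ll.max(axis=1, keepdims=True)
    q = np.exp(ll)
    q /= q.sum(axis=1, keepdims=True)
    n_scored = (queries.calls[:, :, 0] != MISSING).sum(axis=1)
    return PosteriorMatrix(
        individual_ids=list(queries.individual_ids),
        unit_ids=list(baseline.pop_ids),
        q=q,
        n_scored=n_scored,
        level="population",
    )


def aggregate_to_groups(
    posteriors: PosteriorMatrix, hierarchy: BaselineHierarchy
) -> PosteriorMatrix:
    """Sum population posteriors into reporting-group posteriors."""
    if posteriors.level != "population":
        raise ValueError("posteriors already aggregated")
    groups = sorted({hierarchy.group_of(p) for p in posteriors.unit_ids})
    gpos = {g: i for i, g in enumerate(groups)}
    M = np.zeros((len(posteriors.unit_ids), len(groups)))
    for j, pop in enumerate(posteriors.unit_ids):
        M[j, gpos[hierarchy.group_of(pop)]] = 1.0
    return PosteriorMatrix(
        individual_ids=posteriors.individual_ids,
        unit_ids=groups,
        q=posteriors.q @ M,
        n_scored=posteriors.n_scored,
        level="group",
    )


def self_assignment_confusion(
    baseline: BaselineDataset, level: str = "population"
) -> ConfusionMatrix:
    """Leave-one-out jackknife self-assignment confusion matrix."""
    from .io import pool_collections

    queries = pool_collections(baseline.collections, "self")
    home = [c.id for c in baseline.collections for _ in c.individual_ids]
    pm = assignment_posteriors(queries, baseline, leave_one_out=True, home_pops=home)
    if level == "group":
        pm = aggregate_to_groups(pm, baseline.hierarchy)
        truth = [baseline.hierarchy.group_of(p) for p in home]
    elif level == "population":
        truth = home
    else:
        raise ValueError("level must be 'population' or 'group'")
    units = pm.unit_ids
    true_units = sorted(set(truth))
    mat = pd.DataFrame(0, index=true_units, columns=units, dtype=int)
    for t, a in zip(truth, pm.map_units):
        mat.at[t, a] += 1
    return ConfusionMatrix(counts=mat)


# ---------------------------------------------------------------------------
# Mixture estimation


def estimate_mixture(
    posteriors: PosteriorMatrix,
    method: str = "mean-posterior",
    hierarchy: BaselineHierarchy | None = None,
    level: str = "population",
    tol: float = 1e-6,
    max_iter: int = 10000,
) -> MixtureEstimate:
    """Mixture proportions over populations or reporting groups.

    ``mean-posterior`` averages the equal-prior posteriors across individuals.
    ``em`` runs conditional-maximum-likelihood EM on the population-level
    posteriors (row-rescaled likelihoods), then aggregates. Head counts are
    max a posteriori under the method's final priors. Individuals with no
    scored loci are excluded and counted in ``n_excluded``.
    """
    if method not in ("mean-posterior", "em"):
        raise ValueError(f"unknown method {method!r}")
    if level == "group" and hierarchy is None:
        raise ValueError("group-level estimate requires a hierarchy")
    keep = ~posteriors.unassignable
    Q = posteriors.q[keep]
    M = Q.shape[0]
    if M == 0:
        raise ValueError("no assignable individuals in the mixture")
    U = Q.shape[1]
    n_iter = 0
    converged = True
    if method == "mean-posterior":
        pi_pop = Q.mean(axis=0)
        weights = np.ones(U) / U
    else:
        pi_pop = np.full(U, 1.0 / U)
        prev_ll = -np.inf
        converged = False
        for n_iter in range(1, max_iter + 1):
            W = pi_pop[None, :] * Q
            s = W.sum(axis=1, keepdims=True)
            ll = float(np.log(s).sum())
            if ll + 1e-12 < prev_ll:
                raise AssertionError("EM log-likelihood decreased")
            prev_ll = ll
            new_pi = (W / s).mean(axis=0)
            if np.max(np.abs(new_pi - pi_pop)) < tol:
                pi_pop = new_pi
                converged = True
                break
            pi_pop = new_pi
        weights = pi_pop
    # MAP counts under the method's final priors
    post = weights[None, :] * Q
    post /= post.sum(axis=1, keepdims=True)
    map_pop = post.argmax(axis=1)
    counts_pop = np.bincount(map_pop, minlength=U)

    if level == "population":
        unit_ids = list(posteriors.unit_ids)
        pi, counts = pi_pop, counts_pop
    else:
        groups = sorted({hierarchy.group_of(p) for p in posteriors.unit_ids})
        gpos = {g: i for i, g in enumerate(groups)}
        pi = np.zeros(len(groups))
        counts = np.zeros(len(groups), dtype=int)
        for j, pop in enumerate(posteriors.unit_ids):
            gi = gpos[hierarchy.group_of(pop)]
            pi[gi] += pi_pop[j]
            counts[gi] += counts_pop[j]
        unit_ids = groups
    return MixtureEstimate(
        unit_ids=unit_ids,
        proportions=pi / pi.sum(),
        counts=counts,
        method=method,
        level=level,
        n_individuals=M,
        n_excluded=int((~keep).sum()),
        n_iter=n_iter,
        converged=converged,
    )


def report_major_contributors(
    estimate: MixtureEstimate, threshold: float = 0.10
) -> pd.DataFrame:
    """All units with a 'major' flag for contributions at or above ``threshold``.

    The conventional cutoff is a 10% genetic contribution; every unit stays in
    the table so minor contributors remain visible.
    """
    if not (0 <= threshold < 1):
        raise ValueError("threshold must be in [0, 1)")
    df = estimate.to_frame()
    df["major"] = df["proportion"] >= threshold if threshold > 0 else True
    return df.sort_values("proportion", ascending=False, ignore_index=True)
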