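"""Diversity and differentiation statistics.

Implements per-population allele frequency tables, unbiased expected
heterozygosity (Nei's gene diversity with the 2n/(2n-1) small-sample
correction), hypergeometric rarefaction of allelic richness to a fixed number
of gene copies, Weir–Cockerham variance-component estimators of F_ST (theta)
and F_IS (f), and permutation replacements for the classical exact tests:
a genic G-test permuting whole multilocus genotypes between collections,
a one-sided heterozygote-deficit test randomizing alleles among individuals
within a collection, and a two-locus composite linkage-disequilibrium G-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import MISSING, GenotypeCollection

__all__ = [
    "AlleleFrequencyTable",
    "DiversitySummary",
    "FStatResult",
    "PermutationTestResult",
    "allele_counts",
    "diversity_summary",
    "weir_cockerham",
    "pairwise_fst",
    "fis_estimate",
    "genic_differentiation_test",
    "permutation_fis_test",
    "ld_permutation_test",
    "bonferroni_alpha",
]


@dataclass
class AlleleFrequencyTable:
    """Allele counts and totals per population x locus.

    ``counts[p, l, a]`` is the number of gene copies of allele ``a`` at locus
    ``l`` in population ``p``; ``totals[p, l]`` is twice the number of
    individuals scored there. Missing genotypes never contribute.
    """

    pop_ids: list[str]
    loci: list
    counts: np.ndarray  # (P, L, Amax)
    totals: np.ndarray  # (P, L)

    def __post_init__(self) -> None:
        assert np.array_equal(self.counts.sum(axis=2), self.totals)

    @property
    def freqs(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.totals[:, :, None] > 0,
                self.counts / np.maximum(self.totals, 1)[:, :, None],
                np.nan,
            )


def _counts_one(coll: GenotypeCollection, amax: int) -> tuple[np.ndarray, np.ndarray]:
    L = coll.n_loci
    counts = np.zeros((L, amax), dtype=np.int64)
    for l in range(L):
        vals = coll.calls[:, l, :].ravel()
        vals = vals[vals != MISSING]
        if vals.size:
            counts[l, : vals.max() + 1] = np.bincount(vals)[: amax]
    return counts, counts.sum(axis=1)


def allele_counts(collections) -> AlleleFrequencyTable:
    """Tabulate allele counts for one collection or a list sharing a registry."""
    if isinstance(collections, GenotypeCollection):
        collections = [collections]
    else:
        collections = list(collections)
    loci = collections[0].loci
    for c in collections[1:]:
        if c.loci != loci:
            raise ValueError("collections do not share a locus registry")
    amax = max(loc.k for loc in loci)
    counts = np.zeros((len(collections), len(loci), amax), dtype=np.int64)
    for p, c in enumerate(collections):
        counts[p], _ = _counts_one(c, amax)
    return AlleleFrequencyTable(
        pop_ids=[c.id for c in collections],
        loci=loci,
        counts=counts,
        totals=counts.sum(axis=2),
    )


# ---------------------------------------------------------------------------
# Diversity


@dataclass
class DiversitySummary:
    """Per-locus and mean expected heterozygosity and rarefied allelic richness."""

    pop_id: str
    per_locus: pd.DataFrame  # columns: locus, n, H_S, AR, g_used
    mean_hs: float
    mean_ar: float
    g: int  # requested rarefaction size, in gene copies


def _log_comb(n: np.ndarray, k: int) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefied_allelic_richness(counts: np.ndarray, g: int) -> float:
    """Expected allele count in a random subsample of ``g`` gene copies.

    AR(g) = sum_a [1 - C(N - N_a, g) / C(N, g)], the hypergeometric
    probability that each allele appears at least once.
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    N = int(counts.sum())
    if N == 0:
        return float("nan")
    if g < 1:
        raise ValueError("rarefaction size must be >= 1 gene copy")
    g = min(g, N)
    rest = N - counts
    prob_absent = np.zeros(len(counts))
    ok = rest >= g
    if ok.any():
        prob_absent[ok] = np.exp(_log_comb(rest[ok].astype(float), g) - _log_comb(np.array(float(N)), g))
    return float(np.sum(1.0 - prob_absent))


def diversity_summary(
    coll: GenotypeCollection, g: int = 24, unbiased: bool = True
) -> DiversitySummary:
    """Expected heterozygosity and allelic richness per locus and on average.

    ``g`` is the rarefaction size in gene copies (the conventional "minimum
    sample size of 12 individuals" is ``g = 24``); loci with fewer scored
    copies are rarefied to their own total.
    """
    if g < 1:
        raise ValueError("g must be >= 1")
    amax = max(loc.k for loc in coll.loci)
    counts, totals = _counts_one(coll, amax)
    rows = []
    for l, loc in enumerate(coll.loci):
        N = int(totals[l])
        n = N // 2
        if N == 0:
            rows.append((loc.name, 0, np.nan, np.nan, 0))
            continue
        p = counts[l] / N
        hs = 1.0 - float(np.sum(p**2))
        if unbiased and N > 1:
            hs *= N / (N - 1)
        g_used = min(g, N)
        ar = rarefied_allelic_richness(counts[l], g_used)
        rows.append((loc.name, n, hs, ar, g_used))
    df = pd.DataFrame(rows, columns=["locus", "n", "H_S", "AR", "g_used"])
    return DiversitySummary(
        pop_id=coll.id,
        per_locus=df,
        mean_hs=float(df["H_S"].mean()),
        mean_ar=float(df["AR"].mean()),
        g=g,
    )


# ---------------------------------------------------------------------------
# Weir-Cockerham variance components


@dataclass
class FStatResult:
    """Multilocus theta (F_ST) and f (F_IS) as ratios of summed components."""

    theta: float
    f: float
    per_locus: pd.DataFrame  # locus, a, b, c, theta_l
    undefined: bool = False


def _component_arrays(collections: list[GenotypeCollection]):
    """Per-population scored-n, allele frequency and heterozygote-carrier
    frequency arrays, shaped (P, L) and (P, L, Amax)."""
    loci = collections[0].loci
    amax = max(loc.k for loc in loci)
    P, L = len(collections), len(loci)
    n = np.zeros((P, L), dtype=np.int64)
    freq = np.zeros((P, L, amax))
    het = np.zeros((P, L, amax))
    for p, c in enumerate(collections):
        counts, totals = _counts_one(c, amax)
        n[p] = totals // 2
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[p] = np.where(totals[:, None] > 0, counts / np.maximum(totals, 1)[:, None], 0.0)
        for l in range(L):
            a0, a1 = c.calls[:, l, 0], c.calls[:, l, 1]
            hmask = (a0 != a1) & (a0 != MISSING)
            if hmask.any() and n[p, l] > 0:
                hc = np.bincount(
                    np.concatenate([a0[hmask], a1[hmask]]), minlength=amax
                )[:amax]
                het[p, l] = hc / n[p, l]
    return n, freq, het


def weir_cockerham(collections: list[GenotypeCollection]) -> FStatResult:
    """Weir–Cockerham multilocus theta and f.

    Variance components a (among populations), b (among individuals within
    populations) and c (within individuals) are computed per locus x allele and
    pooled over alleles and loci before the ratios (ratio of sums):
    theta = sum(a) / sum(a + b + c), f = 1 - sum(c) / sum(b + c).
    Per locus, only populations with at least one scored individual enter.
    """
    if len(collections) < 2:
        raise ValueError("need >= 2 collections")
    loci = collections[0].loci
    for c in collections[1:]:
        if c.loci != loci:
            raise ValueError("collections do not share a locus registry")
    n, freq, het = _component_arrays(collections)
    rows = []
    A_sum = B_sum = C_sum = 0.0
    for l, loc in enumerate(loci):
        use = n[:, l] > 0
        r = int(use.sum())
        if r < 2:
            continue
        ni = n[use, l].astype(float)
        p = freq[use, l, :]  # (r, A)
        h = het[use, l, :]
        nbar = ni.mean()
        if nbar <= 1:
            continue
        rn = r * nbar
        nc = (rn - np.sum(ni**2) / rn) / (r - 1)
        pbar = (ni[:, None] * p).sum(axis=0) / rn
        s2 = (ni[:, None] * (p - pbar[None, :]) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (ni[:, None] * h).sum(axis=0) / rn
        inner = pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4
        a = (nbar / nc) * (s2 - inner / (nbar - 1))
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        al, bl, cl = float(a.sum()), float(b.sum()), float(c.sum())
        denom = al + bl + cl
        rows.append((loc.name, al, bl, cl, al / denom if denom != 0 else np.nan))
        A_sum += al
        B_sum += bl
        C_sum += cl
    per_locus = pd.DataFrame(rows, columns=["locus", "a", "b", "c", "theta_l"])
    denom = A_sum + B_sum + C_sum
    bc = B_sum + C_sum
    undefined = denom == 0
    theta = A_sum / denom if denom != 0 else np.nan
    f = 1.0 - C_sum / bc if bc != 0 else np.nan
    return FStatResult(theta=theta, f=f, per_locus=per_locus, undefined=undefined)


def pairwise_fst(collections: list[GenotypeCollection]) -> pd.DataFrame:
    """Symmetric matrix of two-population Weir–Cockerham theta, zero diagonal."""
    ids = [c.id for c in collections]
    P = len(ids)
    mat = np.zeros((P, P))
    for i in range(P):
        for j in range(i + 1, P):
            th = weir_cockerham([collections[i], collections[j]]).theta
            mat[i, j] = mat[j, i] = th
    return pd.DataFrame(mat, index=ids, columns=ids)


def _fis_components(n, freq, het) -> tuple[float, float]:
    """Single-population b and c sums (r = 1 specialisation)."""
    B_sum = C_sum = 0.0
    L = n.shape[0]
    for l in range(L):
        ni = float(n[l])
        if ni <= 1:
            continue
        p = freq[l]
        h = het[l]
        b = (ni / (ni - 1)) * (p * (1 - p) - (2 * ni - 1) / (4 * ni) * h)
        c = h / 2
        B_sum += float(b.sum())
        C_sum += float(c.sum())
    return B_sum, C_sum


def fis_estimate(coll: GenotypeCollection) -> float:
    """Multilocus Weir–Cockerham f for a single collection (NaN if monomorphic)."""
    n, freq, het = _component_arrays([coll])
    B, C = _fis_components(n[0], freq[0], het[0])
    bc = B + C
    return 1.0 - C / bc if bc != 0 else float("nan")


# ---------------------------------------------------------------------------
# Permutation tests


@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_perm: int
    seed: int
    flag: str = ""
    per_locus: pd.DataFrame | None = field(default=None, repr=False)


def _individual_allele_counts(coll_calls: np.ndarray, amax: int) -> np.ndarray:
    """(n, L, Amax) per-individual gene-copy counts (0/1/2), missing = all zero."""
    n, L, _ = coll_calls.shape
    out = np.zeros((n, L, amax), dtype=np.int16)
    for l in range(L):
        for side in (0, 1):
            col = coll_calls[:, l, side]
            ok = col != MISSING
            np.add.at(out[:, l, :], (np.nonzero(ok)[0], col[ok]), 1)
    return out


def _g_stat_tables(tA: np.ndarray, tB: np.ndarray) -> np.ndarray:
    """Per-locus G statistic of the stacked 2 x Amax allele-count tables."""
    rowA = tA.sum(axis=1, keepdims=True).astype(float)
    rowB = tB.sum(axis=1, keepdims=True).astype(float)
    col = (tA + tB).astype(float)
    grand = rowA + rowB
    with np.errstate(invalid="ignore", divide="ignore"):
        eA = rowA * col / np.maximum(grand, 1)
        eB = rowB * col / np.maximum(grand, 1)
        termA = np.where(tA > 0, tA * np.log(np.maximum(tA, 1e-300) / np.maximum(eA, 1e-300)), 0.0)
        termB = np.where(tB > 0, tB * np.log(np.maximum(tB, 1e-300) / np.maximum(eB, 1e-300)), 0.0)
    return 2.0 * (termA.sum(axis=1) + termB.sum(axis=1))


def genic_differentiation_test(
    collA: GenotypeCollection,
    collB: GenotypeCollection,
    n_perm: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """Genic differentiation between two collections.

    The statistic is the sum over loci of the G log-likelihood-ratio of the
    2 x k allele-count table; the null distribution permutes whole multilocus
    genotypes between the collections, preserving within-individual structure.
    """
    if collA.loci != collB.loci:
        raise ValueError("collections do not share a locus registry")
    if collA.n_individuals == 0 or collB.n_individuals == 0:
        raise ValueError("empty collection")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    amax = max(loc.k for loc in collA.loci)
    calls = np.concatenate([collA.calls, collB.calls], axis=0)
    C = _individual_allele_counts(calls, amax)
    nA = collA.n_individuals
    n = calls.shape[0]
    obs_l = _g_stat_tables(C[:nA].sum(axis=0), C[nA:].sum(axis=0))
    obs = float(obs_l.sum())
    rng = np.random.default_rng(seed)
    geq = 0
    geq_l = np.zeros(len(obs_l), dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gl = _g_stat_tables(C[perm[:nA]].sum(axis=0), C[perm[nA:]].sum(axis=0))
        geq += gl.sum() >= obs
        geq_l += gl >= obs_l
    per_locus = pd.DataFrame(
        {
            "locus": [loc.name for loc in collA.loci],
            "G": obs_l,
            "p": (1 + geq_l) / (n_perm + 1),
        }
    )
    return PermutationTestResult(
        statistic=obs,
        p_value=(1 + geq) / (n_perm + 1),
        n_perm=n_perm,
        seed=seed,
        per_locus=per_locus,
    )


def permutation_fis_test(
    coll: GenotypeCollection, n_perm: int = 999, seed: int = 0
) -> PermutationTestResult:
    """One-sided heterozygote-deficit test (f > 0).

    Null: alleles are randomized among scored individuals within the
    collection, per locus — Hardy–Weinberg random union of the observed
    gene pool.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    n, freq, het = _component_arrays([coll])
    B, C = _fis_components(n[0], freq[0], het[0])
    if B + C == 0:
        return PermutationTestResult(
            statistic=float("nan"), p_value=1.0, n_perm=n_perm, seed=seed,
            flag="monomorphic",
        )
    obs = 1.0 - C / (B + C)
    rng = np.random.default_rng(seed)
    L = coll.n_loci
    pools = []
    scored_rows = []
    for l in range(L):
        ok = coll.calls[:, l, 0] != MISSING
        scored_rows.append(np.nonzero(ok)[0])
        pools.append(coll.calls[ok, l, :].ravel().copy())
    geq = 0
    calls = coll.calls.copy()
    for _ in range(n_perm):
        perm_calls = calls.copy()
        for l in range(L):
            pool = pools[l]
            if pool.size == 0:
                continue
            shuffled = rng.permutation(pool)
            perm_calls[scored_rows[l], l, :] = shuffled.reshape(-1, 2)
        pc = GenotypeCollection(
            id="perm", individual_ids=list(coll.individual_ids),
            loci=coll.loci, calls=perm_calls,
        )
        npc, fpc, hpc = _component_arrays([pc])
        Bp, Cp = _fis_components(npc[0], fpc[0], hpc[0])
        fp = 1.0 - Cp / (Bp + Cp) if (Bp + Cp) != 0 else 0.0
        geq += fp >= obs
    return PermutationTestResult(
        statistic=obs, p_value=(1 + geq) / (n_perm + 1), n_perm=n_perm, seed=seed
    )


def ld_permutation_test(
    coll: GenotypeCollection,
    locus_a: str,
    locus_b: str,
    n_perm: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """Composite linkage-disequilibrium test between two loci.

    The statistic is the G of the two-locus genotype contingency table over
    individuals scored at both; the null permutes the locus-B genotype column.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    la = coll._locus_index(locus_a)
    lb = coll._locus_index(locus_b)
    ok = (coll.calls[:, la, 0] != MISSING) & (coll.calls[:, lb, 0] != MISSING)
    ga = np.sort(coll.calls[ok, la, :], axis=1)
    gb = np.sort(coll.calls[ok, lb, :], axis=1)
    _, ca = np.unique(ga, axis=0, return_inverse=True)
    _, cb = np.unique(gb, axis=0, return_inverse=True)
    ka, kb = ca.max(initial=-1) + 1, cb.max(initial=-1) + 1
    if ka <= 1 or kb <= 1:
        return PermutationTestResult(
            statistic=0.0, p_value=1.0, n_perm=n_perm, seed=seed, flag="monomorphic"
        )

    def g_of(cb_col: np.ndarray) -> float:
        tab = np.zeros((ka, kb))
        np.add.at(tab, (ca, cb_col), 1)
        row = tab.sum(axis=1, keepdims=True)
        colm = tab.sum(axis=0, keepdims=True)
        e = row * colm / tab.sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            term = np.where(tab > 0, tab * np.log(tab / np.maximum(e, 1e-300)), 0.0)
        return float(2.0 * term.sum())

    obs = g_of(cb)
    rng = np.random.default_rng(seed)
    geq = sum(g_of(rng.permutation(cb)) >= obs for _ in range(n_perm))
    return PermutationTestResult(
        statistic=obs, p_value=(1 + geq) / (n_perm + 1), n_perm=n_perm, seed=seed
    )


def bonferroni_alpha(alpha: float, n_tests: int) -> float:
    """Bonferroni-corrected per-test significance level, alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
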