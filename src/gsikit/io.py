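"""Genotype and hierarchy input/output.

Diploid multilocus genotypes are held in :class:`GenotypeCollection` objects:
a ``(n_individuals, n_loci, 2)`` integer array of allele *indices* into a
per-locus allele registry, with ``MISSING = -1`` marking unscored loci (both
chromosomes missing together). Allele labels are raw integer codes —
microsatellite fragment sizes as standardized by the genotyping consortium —
and are never re-binned.

The on-disk format is GENEPOP (2- or 3-digit allele coding, ``0`` = missing),
plus a tab-separated population → reporting-group hierarchy table with an
optional sister-group tag column.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

MISSING: int = -1

__all__ = [
    "MISSING",
    "Locus",
    "GenotypeCollection",
    "BaselineHierarchy",
    "BaselineDataset",
    "GenepopParseError",
    "read_genepop",
    "write_genepop",
    "load_hierarchy",
    "write_hierarchy",
    "resolve_population_ids",
    "pool_collections",
    "merge_loci",
    "remap_collection",
    "assemble_dataset",
]


class GenepopParseError(ValueError):
    """Malformed GENEPOP input (message names the offending line)."""


@dataclass(frozen=True)
class Locus:
    """A locus with its ordered allele registry.

    ``alleles`` holds the distinct allele codes observed across the whole
    dataset union at this locus, sorted ascending. ``k`` (the registry length)
    is the allele-class count used by the assignment prior.
    """

    name: str
    alleles: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.alleles) < 1:
            raise ValueError(f"locus {self.name!r}: empty allele registry")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"locus {self.name!r}: duplicate allele labels")

    @property
    def k(self) -> int:
        return len(self.alleles)

    def index_of(self, code: int) -> int:
        return self.alleles.index(code)


@dataclass
class GenotypeCollection:
    """A named set of diploid multilocus genotypes.

    ``calls[i, l]`` is an unordered pair of allele indices into
    ``loci[l].alleles``, or ``(MISSING, MISSING)``.
    """

    id: str
    individual_ids: list[str]
    loci: list[Locus]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int32)
        n, L = len(self.individual_ids), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"collection {self.id!r}: calls shape {self.calls.shape} != {(n, L, 2)}"
            )
        half = (self.calls == MISSING).sum(axis=2)
        if np.any(half == 1):
            raise ValueError(f"collection {self.id!r}: half-missing genotype entry")
        for l, locus in enumerate(self.loci):
            col = self.calls[:, l, :]
            if col.size and col.max(initial=MISSING) >= locus.k:
                raise ValueError(
                    f"collection {self.id!r}: allele index out of registry at locus {locus.name!r}"
                )

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def subset_loci(self, names: list[str]) -> "GenotypeCollection":
        """Restrict to the named loci (order follows ``names``)."""
        idx = [self._locus_index(nm) for nm in names]
        return GenotypeCollection(
            id=self.id,
            individual_ids=list(self.individual_ids),
            loci=[self.loci[i] for i in idx],
            calls=self.calls[:, idx, :].copy(),
        )

    def drop_loci(self, names: list[str]) -> "GenotypeCollection":
        keep = [loc.name for loc in self.loci if loc.name not in set(names)]
        return self.subset_loci(keep)

    def _locus_index(self, name: str) -> int:
        for i, loc in enumerate(self.loci):
            if loc.name == name:
                return i
        raise KeyError(f"locus {name!r} not in collection {self.id!r}")


@dataclass
class BaselineHierarchy:
    """Population → reporting-group map with an optional symmetric sister relation."""

    pop_to_group: dict[str, str]
    sisters: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, sibs in self.sisters.items():
            if g in sibs:
                raise ValueError(f"group {g!r} listed as its own sister")
            for s in sibs:
                if g not in self.sisters.get(s, frozenset()):
                    raise ValueError(f"sister relation not symmetric: {g!r} ~ {s!r}")

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.pop_to_group.values()))

    def group_of(self, pop: str) -> str:
        try:
            return self.pop_to_group[pop]
        except KeyError:
            raise KeyError(f"population {pop!r} absent from hierarchy") from None

    def sisters_of(self, group: str) -> frozenset[str]:
        return self.sisters.get(group, frozenset())


@dataclass
class BaselineDataset:
    """Baseline collections sharing one locus registry, plus their hierarchy."""

    collections: list[GenotypeCollection]
    hierarchy: BaselineHierarchy
    loci: list[Locus]

    def __post_init__(self) -> None:
        ids = [c.id for c in self.collections]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate collection ids in baseline")
        for c in self.collections:
            if c.loci != self.loci:
                raise ValueError(
                    f"collection {c.id!r} does not share the dataset locus registry"
                )
            self.hierarchy.group_of(c.id)  # raises if unmapped

    @property
    def pop_ids(self) -> list[str]:
        return [c.id for c in self.collections]

    def collection(self, pop_id: str) -> GenotypeCollection:
        for c in self.collections:
            if c.id == pop_id:
                return c
        raise KeyError(f"population {pop_id!r} not in baseline")


# ---------------------------------------------------------------------------
# GENEPOP reading/writing


def read_genepop(
    path,
    allele_digits: int = 3,
    pop_ids: list[str] | None = None,
) -> tuple[list[GenotypeCollection], list[Locus]]:
    """Read a GENEPOP file into one collection per POP block.

    Allele code 0 means missing; a half-missing entry is coerced to fully
    missing. The shared registry is the union of observed nonzero codes per
    locus, sorted ascending. Population ids default to the GENEPOP convention
    (label of the last individual in each block) unless ``pop_ids`` supplies
    them by block order.
    """
    if allele_digits not in (2, 3):
        raise ValueError("allele_digits must be 2 or 3")
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenepopParseError("empty GENEPOP file")

    def is_pop(line: str) -> bool:
        return line.strip().lower() == "pop"

    locus_names: list[str] = []
    i = 1  # line 0 is the title
    while i < len(lines) and not is_pop(lines[i]):
        for nm in lines[i].split(","):
            if nm.strip():
                locus_names.append(nm.strip())
        i += 1
    if i == len(lines):
        raise GenepopParseError("no POP separator found")
    L = len(locus_names)

    blocks: list[tuple[list[str], list[list[tuple[int, int]]]]] = []
    cur_ids: list[str] = []
    cur_rows: list[list[tuple[int, int]]] = []
    width = 2 * allele_digits
    for ln in range(i, len(lines)):
        line = lines[ln]
        if not line.strip():
            continue
        if is_pop(line):
            if cur_ids or blocks or ln == i:
                if ln != i:
                    blocks.append((cur_ids, cur_rows))
                cur_ids, cur_rows = [], []
            continue
        if "," not in line:
            raise GenepopParseError(f"line {ln + 1}: missing ',' after individual label")
        label, rest = line.split(",", 1)
        tokens = rest.split()
        if len(tokens) != L:
            raise GenepopParseError(
                f"line {ln + 1}: expected {L} genotypes, found {len(tokens)}"
            )
        row: list[tuple[int, int]] = []
        for tok in tokens:
            if len(tok) != width or not tok.isdigit():
                raise GenepopParseError(
                    f"line {ln + 1}: genotype token {tok!r} is not "
                    f"{width} digits ({allele_digits}-digit coding)"
                )
            a, b = int(tok[:allele_digits]), int(tok[allele_digits:])
            if a == 0 or b == 0:
                row.append((0, 0))
            else:
                row.append((a, b))
        cur_ids.append(label.strip())
        cur_rows.append(row)
    blocks.append((cur_ids, cur_rows))
    blocks = [b for b in blocks if b[0]]
    if not blocks:
        raise GenepopParseError("no individuals found after POP separators")

    # union registry per locus
    observed: list[set[int]] = [set() for _ in range(L)]
    for _, rows in blocks:
        for row in rows:
            for l, (a, b) in enumerate(row):
                if a != 0:
                    observed[l].update((a, b))
    loci = [
        Locus(name=nm, alleles=tuple(sorted(obs)) if obs else (0,))
        for nm, obs in zip(locus_names, observed)
    ]
    lookup = [{code: j for j, code in enumerate(loc.alleles)} for loc in loci]

    if pop_ids is not None and len(pop_ids) != len(blocks):
        raise ValueError(f"pop_ids has {len(pop_ids)} entries for {len(blocks)} POP blocks")
    collections = []
    for b, (ids, rows) in enumerate(blocks):
        calls = np.full((len(ids), L, 2), MISSING, dtype=np.int32)
        for idx, row in enumerate(rows):
            for l, (a, bb) in enumerate(row):
                if a != 0:
                    calls[idx, l, 0] = lookup[l][a]
                    calls[idx, l, 1] = lookup[l][bb]
        cid = pop_ids[b] if pop_ids is not None else ids[-1]
        collections.append(
            GenotypeCollection(id=cid, individual_ids=ids, loci=loci, calls=calls)
        )
    cids = [c.id for c in collections]
    if len(set(cids)) != len(cids):
        raise GenepopParseError(
            "duplicate population ids resolved from POP blocks; pass pop_ids explicitly"
        )
    return collections, loci


def write_genepop(
    collections: list[GenotypeCollection],
    path,
    allele_digits: int = 3,
    title: str = "gsikit export",
) -> None:
    """Write collections (sharing one registry) to a GENEPOP file."""
    if allele_digits not in (2, 3):
        raise ValueError("allele_digits must be 2 or 3")
    loci = collections[0].loci
    for c in collections[1:]:
        if c.loci != loci:
            raise ValueError("collections do not share a locus registry")
    limit = 10**allele_digits
    for loc in loci:
        if any(code >= limit or code < 0 for code in loc.alleles):
            raise ValueError(
                f"locus {loc.name!r}: allele label not representable in "
                f"{allele_digits} digits"
            )
    d = allele_digits
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for loc in loci:
            fh.write(loc.name + "\n")
        for coll in collections:
            fh.write("POP\n")
            for i, ind in enumerate(coll.individual_ids):
                toks = []
                for l, loc in enumerate(loci):
                    a, b = coll.calls[i, l]
                    if a == MISSING:
                        toks.append("0" * (2 * d))
                    else:
                        toks.append(f"{loc.alleles[a]:0{d}d}{loc.alleles[b]:0{d}d}")
                fh.write(f"{ind} ,  " + " ".join(toks) + "\n")


# ---------------------------------------------------------------------------
# Hierarchy


def load_hierarchy(path) -> BaselineHierarchy:
    """Load a (population, group[, sister_tag]) TSV into a hierarchy.

    Groups sharing a sister tag become a symmetric sister set. Duplicate
    population rows are rejected.
    """
    pop_to_group: dict[str, str] = {}
    group_tag: dict[str, str] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].lstrip().startswith("#") or not row[0].strip():
                continue
            if len(row) < 2:
                raise ValueError(f"hierarchy row {row!r}: need (population, group)")
            pop, group = row[0].strip(), row[1].strip()
            if pop in pop_to_group:
                raise ValueError(f"duplicate population row {pop!r} in hierarchy")
            pop_to_group[pop] = group
            if len(row) > 2 and row[2].strip():
                tag = row[2].strip()
                if group_tag.get(group, tag) != tag:
                    raise ValueError(f"group {group!r} carries conflicting sister tags")
                group_tag[group] = tag
    tag_groups: dict[str, set[str]] = {}
    for g, t in group_tag.items():
        tag_groups.setdefault(t, set()).add(g)
    sisters: dict[str, frozenset[str]] = {}
    for t, gs in tag_groups.items():
        if len(gs) >= 2:
            for g in gs:
                sisters[g] = frozenset(gs - {g})
    return BaselineHierarchy(pop_to_group=pop_to_group, sisters=sisters)


def write_hierarchy(hierarchy: BaselineHierarchy, path) -> None:
    # invert sister sets to shared tags
    tag_of: dict[str, str] = {}
    seen: set[frozenset[str]] = set()
    for g, sibs in hierarchy.sisters.items():
        clique = frozenset(sibs | {g})
        if clique not in seen:
            seen.add(clique)
            tag = "sis_" + "_".join(sorted(clique))
            for m in clique:
                tag_of[m] = tag
    with open(path, "w") as fh:
        for pop, group in hierarchy.pop_to_group.items():
            tag = tag_of.get(group, "")
            fh.write(f"{pop}\t{group}\t{tag}\n" if tag else f"{pop}\t{group}\n")


# ---------------------------------------------------------------------------
# Pooling and registry merging


def pool_collections(
    collections: list[GenotypeCollection], new_id: str
) -> GenotypeCollection:
    """Concatenate collections sharing a registry; allele counts are additive."""
    if not collections:
        raise ValueError("nothing to pool")
    loci = collections[0].loci
    for c in collections[1:]:
        if c.loci != loci:
            raise ValueError("cannot pool collections with mismatched locus registries")
    return GenotypeCollection(
        id=new_id,
        individual_ids=[i for c in collections for i in c.individual_ids],
        loci=loci,
        calls=np.concatenate([c.calls for c in collections], axis=0),
    )


def merge_loci(*loci_lists: list[Locus]) -> list[Locus]:
    """Union the allele registries of locus lists sharing the same locus names."""
    names = [loc.name for loc in loci_lists[0]]
    for other in loci_lists[1:]:
        if [loc.name for loc in other] != names:
            raise ValueError("locus name lists differ; cannot merge registries")
    merged = []
    for l, name in enumerate(names):
        union: set[int] = set()
        for lst in loci_lists:
            union.update(lst[l].alleles)
        union.discard(0)
        merged.append(Locus(name=name, alleles=tuple(sorted(union)) if union else (0,)))
    return merged


def remap_collection(
    coll: GenotypeCollection, new_loci: list[Locus]
) -> GenotypeCollection:
    """Re-index calls onto a (super)registry containing all observed alleles."""
    if [l.name for l in new_loci] != [l.name for l in coll.loci]:
        raise ValueError("locus names differ; cannot remap")
    calls = np.full_like(coll.calls, MISSING)
    for l, (old, new) in enumerate(zip(coll.loci, new_loci)):
        pos = {code: j for j, code in enumerate(new.alleles)}
        table = np.full(old.k, -2, dtype=np.int32)
        for j, code in enumerate(old.alleles):
            if code in pos:
                table[j] = pos[code]
        called = coll.calls[:, l, :][coll.calls[:, l, :] >= 0]
        if called.size:
            bad = {old.alleles[j] for j in np.unique(called) if table[j] == -2}
            if bad:
                raise ValueError(
                    f"registry for locus {new.name!r} lacks called alleles {sorted(bad)}"
                )
        for i in (0, 1):
            col = coll.calls[:, l, i]
            ok = col >= 0
            if ok.any():
                calls[ok, l, i] = table[col[ok]]
    return GenotypeCollection(
        id=coll.id,
        individual_ids=list(coll.individual_ids),
        loci=new_loci,
        calls=calls,
    )


def resolve_population_ids(
    collections: list[GenotypeCollection], hierarchy: BaselineHierarchy
) -> list[GenotypeCollection]:
    """Reconcile GENEPOP block ids with the hierarchy.

    If the default ids (last individual label per block) are all present in
    the hierarchy they are kept; otherwise the hierarchy's populations are
    assigned to the blocks by order, which must then match in number.
    """
    if all(c.id in hierarchy.pop_to_group for c in collections):
        return collections
    ids = list(hierarchy.pop_to_group)
    if len(ids) != len(collections):
        raise ValueError(
            f"cannot resolve population ids: {len(collections)} POP blocks but "
            f"{len(ids)} hierarchy populations, and block labels are not all mapped"
        )
    for c, pid in zip(collections, ids):
        c.id = pid
    return collections


def assemble_dataset(
    collections: list[GenotypeCollection],
    hierarchy: BaselineHierarchy,
    extra_loci: list[list[Locus]] | None = None,
) -> BaselineDataset:
    """Build a baseline: union registries (optionally over mixture registries too,
    so query-only alleles get zero baseline counts), remap, and validate the
    hierarchy covers every collection."""
    all_loci = [c.loci for c in collections] + list(extra_loci or [])
    union = merge_loci(*all_loci)
    remapped = [remap_collection(c, union) for c in collections]
    missing = [c.id for c in remapped if c.id not in hierarchy.pop_to_group]
    if missing:
        raise ValueError(f"populations absent from hierarchy: {missing}")
    return BaselineDataset(collections=remapped, hierarchy=hierarchy, loci=union)
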