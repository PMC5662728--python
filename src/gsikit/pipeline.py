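"""End-to-end study orchestration.

``run_study`` executes the full workflow over a baseline, a hierarchy and one
or more mixture files: load and validate, pool collections, diversity and
F-statistics with the popgen locus exclusions, pairwise differentiation
tests, leave-one-out self-assignment, mixture assignment and estimation with
all loci retained, the major-contributor table, and an optional founding
simulation. Every artifact carries the global seed and a hash of the
configuration; a single global seed deterministically spawns per-stage
substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assignment, founding, io, popgen

logger = logging.getLogger("gsikit")

__all__ = ["RunConfig", "run_study"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (paths and analysis parameters)."""

    baseline_path: str
    hierarchy_path: str
    mixture_paths: list[str] = field(default_factory=list)
    allele_digits: int = 3
    baseline_pop_ids: list[str] | None = None
    pool: dict[str, list[str]] = field(default_factory=dict)  # new id -> member ids
    exclude_loci_popgen: list[str] = field(default_factory=list)
    exclude_loci_assignment: list[str] = field(default_factory=list)
    rarefaction_g: int = 24
    n_perm: int = 999
    mixture_method: str = "mean-posterior"
    contribution_threshold: float = 0.10
    founding: dict | None = None  # {source_pop_a, source_pop_b, n_individuals, p_threshold}
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.contribution_threshold < 1):
            raise ValueError("contribution_threshold must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, stamp: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {stamp}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_study(config: RunConfig, outdir) -> dict[str, Path]:
    """Run the whole study; returns a map of artifact name -> path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"config_hash={config.digest()} seed={config.seed}"
    stages = np.random.SeedSequence(config.seed).spawn(4)
    stage_seed = [int(s.generate_state(1)[0] % (2**31)) for s in stages]
    artifacts: dict[str, Path] = {}

    # --- load + validate ---------------------------------------------------
    try:
        collections, _ = io.read_genepop(
            config.baseline_path, config.allele_digits, pop_ids=config.baseline_pop_ids
        )
        hierarchy = io.load_hierarchy(config.hierarchy_path)
        if config.baseline_pop_ids is None:
            collections = io.resolve_population_ids(collections, hierarchy)
        mixtures = []
        for mp in config.mixture_paths:
            mcolls, mloci = io.read_genepop(mp, config.allele_digits)
            pooled = io.pool_collections(mcolls, Path(mp).stem)
            mixtures.append(pooled)
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"stage 'load': {e}") from e

    # --- pooling -----------------------------------------------------------
    if config.pool:
        by_id = {c.id: c for c in collections}
        for new_id, members in config.pool.items():
            merged = io.pool_collections([by_id.pop(m) for m in members], new_id)
            by_id[new_id] = merged
            logger.info("pooled %s -> %s", members, new_id)
        collections = list(by_id.values())
    baseline = io.assemble_dataset(
        collections, hierarchy, extra_loci=[m.loci for m in mixtures] or None
    )
    mixtures = [io.remap_collection(m, baseline.loci) for m in mixtures]

    # --- popgen stage (with its exclusions) --------------------------------
    try:
        keep = [l.name for l in baseline.loci if l.name not in set(config.exclude_loci_popgen)]
        logger.info("popgen loci: %s", keep)
        pg_colls = [c.subset_loci(keep) for c in baseline.collections]
        rows = []
        for c in pg_colls:
            ds = popgen.diversity_summary(c, g=config.rarefaction_g)
            rows.append((c.id, c.n_individuals, ds.mean_hs, ds.mean_ar))
        div = pd.DataFrame(rows, columns=["population", "n", "H_S", "AR"])
        _write_tsv(div, out / "diversity.tsv", stamp)
        artifacts["diversity"] = out / "diversity.tsv"

        fst = popgen.pairwise_fst(pg_colls)
        _write_tsv(fst, out / "pairwise_fst.tsv", stamp, index=True)
        artifacts["pairwise_fst"] = out / "pairwise_fst.tsv"

        multi = popgen.weir_cockerham(pg_colls)
        _write_tsv(
            pd.DataFrame({"theta": [multi.theta], "f": [multi.f]}),
            out / "multilocus_fstats.tsv", stamp,
        )
        artifacts["multilocus_fstats"] = out / "multilocus_fstats.tsv"

        tests = []
        for i in range(len(pg_colls)):
            for j in range(i + 1, len(pg_colls)):
                res = popgen.genic_differentiation_test(
                    pg_colls[i], pg_colls[j],
                    n_perm=config.n_perm, seed=stage_seed[0] + i * 1000 + j,
                )
                tests.append(
                    (pg_colls[i].id, pg_colls[j].id, res.statistic, res.p_value,
                     res.n_perm, res.seed)
                )
        n_pairs = len(tests)
        tdf = pd.DataFrame(
            tests, columns=["pop_a", "pop_b", "G", "p", "n_perm", "seed"]
        )
        tdf["bonferroni_alpha"] = popgen.bonferroni_alpha(0.05, max(n_pairs, 1))
        _write_tsv(tdf, out / "differentiation_tests.tsv", stamp)
        artifacts["differentiation_tests"] = out / "differentiation_tests.tsv"
    except RuntimeError:
        raise
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"stage 'popgen': {e}") from e

    # --- self-assignment ---------------------------------------------------
    try:
        conf = assignment.self_assignment_confusion(baseline, level="group")
        _write_tsv(conf.counts, out / "self_assignment_confusion.tsv", stamp, index=True)
        artifacts["self_assignment_confusion"] = out / "self_assignment_confusion.tsv"
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"stage 'self-assignment': {e}") from e

    # --- mixture assignment (all loci retained) -----------------------------
    try:
        keep_assign = [
            l.name for l in baseline.loci
            if l.name not in set(config.exclude_loci_assignment)
        ]
        logger.info("assignment loci: %s", keep_assign)
        a_base = io.BaselineDataset(
            collections=[c.subset_loci(keep_assign) for c in baseline.collections],
            hierarchy=baseline.hierarchy,
            loci=baseline.collections[0].subset_loci(keep_assign).loci,
        )
        for mix in mixtures:
            m = mix.subset_loci(keep_assign)
            pm = assignment.assignment_posteriors(m, a_base)
            excluded = [
                iid for iid, bad in zip(pm.individual_ids, pm.unassignable) if bad
            ]
            if excluded:
                logger.warning("%s: unassignable individuals %s", mix.id, excluded)
            gm = assignment.aggregate_to_groups(pm, a_base.hierarchy)
            _write_tsv(pm.to_frame(), out / f"posteriors_{mix.id}_pop.tsv", stamp, index=True)
            _write_tsv(gm.to_frame(), out / f"posteriors_{mix.id}_group.tsv", stamp, index=True)
            est = assignment.estimate_mixture(
                pm, method=config.mixture_method,
                hierarchy=a_base.hierarchy, level="group",
            )
            table = assignment.report_major_contributors(
                est, threshold=config.contribution_threshold
            )
            _write_tsv(table, out / f"mixture_{mix.id}.tsv", stamp)
            artifacts[f"mixture_{mix.id}"] = out / f"mixture_{mix.id}.tsv"
    except RuntimeError:
        raise
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"stage 'mixture': {e}") from e

    # --- founding simulation -----------------------------------------------
    if config.founding:
        try:
            fspec = founding.FoundingSpec(
                source_pop_a=config.founding["source_pop_a"],
                source_pop_b=config.founding["source_pop_b"],
                n_individuals=int(config.founding.get("n_individuals", 1000)),
                p_threshold=float(config.founding.get("p_threshold", 0.8)),
                seed=stage_seed[3],
            )
            rep = founding.run_founding_simulation(fspec, baseline)
            rep.to_json(out / "founding_sim.json")
            artifacts["founding_sim"] = out / "founding_sim.json"
        except Exception as e:  # noqa: BLE001
            raise RuntimeError(f"stage 'founding-sim': {e}") from e

    meta = {"config": asdict(config), "config_hash": config.digest(), "seed": config.seed}
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    artifacts["run_metadata"] = out / "run_metadata.json"
    return artifacts
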