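import numpy as np
import pytest

from gsikit.io import GenotypeCollection, Locus
from gsikit.synthetic import SyntheticBaselineSpec, generate_baseline

TINY_GENEPOP = """Two populations, three loci
LocA
LocB, LocC
POP
a1 ,  101101 202204 101103
a2 ,  101103 202202 000000
POP
b1 ,  103103 204204 101101
b2 ,  101103 202204 103103
b3 ,  103103 000000 101103
"""


@pytest.fixture
def tiny_genepop(tmp_path):
    path = tmp_path / "tiny.genepop"
    path.write_text(TINY_GENEPOP)
    return path


@pytest.fixture
def one_locus():
    """Registry with two alleles at a single locus."""
    return [Locus("L1", (101, 103))]


def make_collection(cid, genotypes, loci):
    """Build a collection from a list of per-individual index-pair lists."""
    calls = np.array(genotypes, dtype=np.int32)
    return GenotypeCollection(
        id=cid,
        individual_ids=[f"{cid}_{i}" for i in range(len(genotypes))],
        loci=loci,
        calls=calls,
    )


@pytest.fixture(scope="session")
def small_baseline():
    """3 groups x 2 populations, 10 loci, moderate divergence, some missing."""
    spec = SyntheticBaselineSpec(
        n_groups=3, pops_per_group=2, f_between=0.08, f_within=0.01,
        n_loci=10, alleles_per_locus=8, n_per_pop=40, missing_rate=0.03, seed=11,
    )
    dataset, truth = generate_baseline(spec)
    return dataset, truth
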