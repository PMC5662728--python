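import numpy as np
import pytest

from gsikit.io import Locus
from gsikit.popgen import (
    bonferroni_alpha,
    diversity_summary,
    fis_estimate,
    genic_differentiation_test,
    ld_permutation_test,
    pairwise_fst,
    permutation_fis_test,
    rarefied_allelic_richness,
    weir_cockerham,
)
from gsikit.synthetic import SyntheticBaselineSpec, generate_baseline

from conftest import make_collection


class TestDiversity:
    def test_unbiased_gene_diversity_two_heterozygotes(self, one_locus):
        # genotypes {AB, AB}: n = 2, p = (0.5, 0.5), H_S = (4/3) * 0.5
        coll = make_collection("p", [[[0, 1]], [[0, 1]]], one_locus)
        ds = diversity_summary(coll, g=4)
        assert ds.per_locus["H_S"].iloc[0] == pytest.approx(2 / 3, abs=1e-12)

    def test_monomorphic_locus(self):
        loci = [Locus("L1", (101,))]
        coll = make_collection("p", [[[0, 0]]] * 5, loci)
        ds = diversity_summary(coll, g=4)
        assert ds.per_locus["H_S"].iloc[0] == pytest.approx(0.0)
        assert ds.per_locus["AR"].iloc[0] == pytest.approx(1.0)

    def test_rarefaction_at_full_sample_equals_allele_count(self, small_baseline):
        dataset, _ = small_baseline
        coll = dataset.collections[0]
        from gsikit.popgen import allele_counts

        tab = allele_counts(coll)
        for l in range(3):
            N = int(tab.totals[0, l])
            observed = int((tab.counts[0, l] > 0).sum())
            assert rarefied_allelic_richness(tab.counts[0, l], N) == pytest.approx(
                observed, abs=1e-9
            )

    def test_rarefaction_monotone_in_g(self):
        counts = np.array([12, 7, 3, 1, 1])
        ars = [rarefied_allelic_richness(counts, g) for g in range(2, 25)]
        assert all(b >= a - 1e-12 for a, b in zip(ars, ars[1:]))
        assert all(ar <= 5 + 1e-12 for ar in ars)

    def test_invalid_g_rejected(self, one_locus):
        coll = make_collection("p", [[[0, 1]]], one_locus)
        with pytest.raises(ValueError):
            diversity_summary(coll, g=0)


class TestWeirCockerham:
    def test_complete_fixation_theta_one(self, one_locus):
        a = make_collection("a", [[[0, 0]], [[0, 0]]], one_locus)
        b = make_collection("b", [[[1, 1]], [[1, 1]]], one_locus)
        res = weir_cockerham([a, b])
        assert res.theta == pytest.approx(1.0)

    def test_all_heterozygotes_components(self, one_locus):
        # two identical pops of {AB, AB}: per allele a=0, b=-0.25, c=0.5
        a = make_collection("a", [[[0, 1]], [[0, 1]]], one_locus)
        b = make_collection("b", [[[0, 1]], [[0, 1]]], one_locus)
        res = weir_cockerham([a, b])
        assert res.theta == pytest.approx(0.0, abs=1e-12)
        assert res.f == pytest.approx(-1.0, abs=1e-12)
        row = res.per_locus.iloc[0]
        assert row["a"] == pytest.approx(0.0, abs=1e-12)
        assert row["b"] == pytest.approx(-0.5, abs=1e-12)  # summed over 2 alleles
        assert row["c"] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_balding_nichols_recovery(self, seed):
        spec = SyntheticBaselineSpec(
            n_groups=5, pops_per_group=1, f_between=0.05, f_within=0.0,
            n_loci=15, alleles_per_locus=8, n_per_pop=100, seed=seed,
        )
        dataset, _ = generate_baseline(spec)
        theta = weir_cockerham(dataset.collections).theta
        assert 0.03 < theta < 0.07

    def test_pairwise_matrix_symmetric_zero_diagonal(self, small_baseline):
        dataset, _ = small_baseline
        mat = pairwise_fst(dataset.collections[:4])
        arr = mat.to_numpy()
        np.testing.assert_allclose(arr, arr.T)
        np.testing.assert_allclose(np.diag(arr), 0.0)

    def test_duplicated_population_theta_near_zero(self):
        spec = SyntheticBaselineSpec(
            n_groups=1, pops_per_group=1, n_loci=15, alleles_per_locus=8,
            n_per_pop=100, seed=5,
        )
        dataset, _ = generate_baseline(spec)
        coll = dataset.collections[0]
        half_a = make_collection("h1", coll.calls[:50].tolist(), coll.loci)
        half_b = make_collection("h2", coll.calls[50:].tolist(), coll.loci)
        assert abs(weir_cockerham([half_a, half_b]).theta) < 0.02

    def test_monomorphic_dataset_flagged_not_crash(self):
        loci = [Locus("L1", (101,))]
        a = make_collection("a", [[[0, 0]]] * 4, loci)
        b = make_collection("b", [[[0, 0]]] * 4, loci)
        res = weir_cockerham([a, b])
        assert res.undefined
        assert np.isnan(res.theta)


class TestPermutationTests:
    def test_disjoint_fixed_alleles_minimal_p(self, one_locus):
        a = make_collection("a", [[[0, 0]]] * 20, one_locus)
        b = make_collection("b", [[[1, 1]]] * 20, one_locus)
        res = genic_differentiation_test(a, b, n_perm=199, seed=1)
        assert res.p_value == pytest.approx(1 / 200)

    def test_null_p_in_unit_interval_and_reproducible(self, small_baseline):
        dataset, _ = small_baseline
        a, b = dataset.collections[0], dataset.collections[1]
        r1 = genic_differentiation_test(a, b, n_perm=199, seed=42)
        r2 = genic_differentiation_test(a, b, n_perm=199, seed=42)
        assert 0 < r1.p_value <= 1
        assert r1.p_value == r2.p_value
        assert len(r1.per_locus) == len(a.loci)

    def test_empty_collection_rejected(self, one_locus):
        from gsikit.io import GenotypeCollection

        a = make_collection("a", [[[0, 0]]], one_locus)
        b = GenotypeCollection(
            id="b", individual_ids=[], loci=one_locus,
            calls=np.empty((0, 1, 2), dtype=np.int32),
        )
        with pytest.raises(ValueError, match="empty"):
            genic_differentiation_test(a, b)

    def test_fis_deficit_detected(self, one_locus):
        # all homozygotes, two alleles at 0.5: extreme heterozygote deficit
        geno = [[[0, 0]]] * 25 + [[[1, 1]]] * 25
        coll = make_collection("selfed", geno, one_locus)
        res = permutation_fis_test(coll, n_perm=199, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value <= 0.05

    def test_fis_monomorphic_flagged(self):
        loci = [Locus("L1", (101,))]
        coll = make_collection("p", [[[0, 0]]] * 10, loci)
        res = permutation_fis_test(coll, n_perm=99, seed=0)
        assert res.p_value == 1.0
        assert res.flag == "monomorphic"

    def test_fis_null_uniformish(self):
        # HWE-sampled population: p should not be systematically small
        spec = SyntheticBaselineSpec(
            n_groups=1, pops_per_group=1, n_loci=10, alleles_per_locus=6,
            n_per_pop=50, seed=3,
        )
        dataset, _ = generate_baseline(spec)
        ps = [
            permutation_fis_test(dataset.collections[0], n_perm=99, seed=s).p_value
            for s in range(5)
        ]
        assert np.mean(ps) > 0.05

    def test_ld_duplicated_locus_minimal_p(self):
        rng = np.random.default_rng(0)
        loci = [Locus("L1", (101, 103)), Locus("L2", (101, 103))]
        g = rng.integers(0, 2, size=(50, 1, 2))
        calls = np.concatenate([g, g], axis=1)  # locus 2 duplicates locus 1
        coll = make_collection("p", calls.tolist(), loci)
        res = ld_permutation_test(coll, "L1", "L2", n_perm=199, seed=1)
        assert res.p_value == pytest.approx(1 / 200)

    def test_ld_independent_loci_not_significant(self):
        rng = np.random.default_rng(7)
        loci = [Locus("L1", (101, 103)), Locus("L2", (101, 103))]
        calls = rng.integers(0, 2, size=(80, 2, 2))
        coll = make_collection("p", calls.tolist(), loci)
        res = ld_permutation_test(coll, "L1", "L2", n_perm=199, seed=2)
        assert res.p_value > 0.01

    def test_ld_monomorphic_flagged(self):
        loci = [Locus("L1", (101,)), Locus("L2", (101, 103))]
        calls = [[[0, 0], [0, 1]]] * 10
        coll = make_collection("p", calls, loci)
        res = ld_permutation_test(coll, "L1", "L2", n_perm=99, seed=0)
        assert res.p_value == 1.0
        assert res.flag == "monomorphic"


class TestBonferroni:
    def test_six_basin_pairs(self):
        assert bonferroni_alpha(0.05, 6) == pytest.approx(0.00833, abs=5e-6)
        assert round(bonferroni_alpha(0.05, 6), 3) == 0.008

    def test_thirty_six_intrabasin_pairs(self):
        assert bonferroni_alpha(0.05, 36) == pytest.approx(0.00139, abs=5e-6)
        assert round(bonferroni_alpha(0.05, 36), 4) == 0.0014

    def test_identity_and_validation(self):
        assert bonferroni_alpha(0.05, 1) == 0.05
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestFisEstimate:
    def test_hwe_mean_near_zero(self):
        vals = []
        for seed in range(10):
            spec = SyntheticBaselineSpec(
                n_groups=1, pops_per_group=1, n_loci=15, alleles_per_locus=8,
                n_per_pop=100, seed=seed,
            )
            dataset, _ = generate_baseline(spec)
            vals.append(fis_estimate(dataset.collections[0]))
        assert abs(np.mean(vals)) < 0.02
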