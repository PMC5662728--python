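import numpy as np
import pytest

from gsikit.assignment import (
    aggregate_to_groups,
    assignment_posteriors,
    estimate_mixture,
    report_major_contributors,
    rm_genotype_probability,
    self_assignment_confusion,
)
from gsikit.evaluation import dirichlet_predictive_by_enumeration
from gsikit.io import (
    BaselineDataset,
    BaselineHierarchy,
    GenotypeCollection,
    Locus,
    pool_collections,
)
from gsikit.assignment import PosteriorMatrix
from gsikit.synthetic import SyntheticBaselineSpec, generate_baseline, generate_mixture

from conftest import make_collection


class TestRMProbability:
    def test_heterozygote_hand_value(self):
        # counts A:9, B:1, k=2: P(AB) = 2 * 9.5 * 1.5 / (11 * 12)
        p = rm_genotype_probability((0, 1), np.array([9.0, 1.0]), k=2)
        assert p == pytest.approx(0.215909, abs=1e-6)

    def test_homozygote_hand_value(self):
        p = rm_genotype_probability((0, 0), np.array([9.0, 1.0]), k=2)
        assert p == pytest.approx(0.755682, abs=1e-6)

    def test_prior_only_zero_counts(self):
        p = rm_genotype_probability((0, 0), np.array([0.0, 0.0]), k=2)
        assert p == pytest.approx(0.375)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_matches_urn_enumeration(self, k):
        rng = np.random.default_rng(k)
        for _ in range(50):
            counts = rng.integers(0, 8, size=k)
            a, b = rng.integers(0, k, size=2)
            closed = rm_genotype_probability((a, b), counts.astype(float), k)
            oracle = dirichlet_predictive_by_enumeration((a, b), counts, k)
            assert closed == pytest.approx(oracle, abs=1e-13)

    def test_genotype_distribution_sums_to_one(self):
        counts = np.array([3.0, 5.0, 0.0])
        total = sum(
            rm_genotype_probability((a, b), counts, 3)
            for a in range(3)
            for b in range(a, 3)
        )
        assert total == pytest.approx(1.0, abs=1e-12)


def _two_pop_baseline(one_locus, calls_a, calls_b):
    a = make_collection("p1", calls_a, one_locus)
    b = make_collection("p2", calls_b, one_locus)
    hier = BaselineHierarchy(pop_to_group={"p1": "g1", "p2": "g2"})
    return BaselineDataset(collections=[a, b], hierarchy=hier, loci=one_locus)


class TestPosteriors:
    def test_symmetric_baseline_gives_half(self, one_locus):
        geno = [[[0, 1]]] * 5
        ds = _two_pop_baseline(one_locus, geno, geno)
        q = assignment_posteriors(make_collection("m", [[[0, 0]]], one_locus), ds)
        np.testing.assert_allclose(q.q[0], [0.5, 0.5])
        assert q.tie[0]

    def test_asymmetric_hand_value(self, one_locus):
        # p1 A:9,B:1 vs p2 A:1,B:9; query AA -> q1 = 99.75 / 103.5
        calls_a = [[[0, 0]]] * 4 + [[[0, 1]]]  # A:9 B:1
        calls_b = [[[1, 1]]] * 4 + [[[0, 1]]]  # A:1 B:9
        ds = _two_pop_baseline(one_locus, calls_a, calls_b)
        q = assignment_posteriors(make_collection("m", [[[0, 0]]], one_locus), ds)
        assert q.q[0, 0] == pytest.approx(99.75 / 103.5, abs=1e-9)

    def test_rows_sum_to_one(self, small_baseline):
        dataset, truth = small_baseline
        mix, _ = generate_mixture(truth, {dataset.pop_ids[0]: 1.0}, n=30, seed=9)
        from gsikit.io import assemble_dataset, remap_collection

        ds = assemble_dataset(
            dataset.collections, dataset.hierarchy, extra_loci=[mix.loci]
        )
        mix = remap_collection(mix, ds.loci)
        pm = assignment_posteriors(mix, ds)
        np.testing.assert_allclose(pm.q.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_scored_loci_flagged_unassignable(self, one_locus):
        from gsikit.io import MISSING

        ds = _two_pop_baseline(one_locus, [[[0, 1]]] * 3, [[[0, 0]]] * 3)
        blank = make_collection("m", [[[MISSING, MISSING]]], one_locus)
        pm = assignment_posteriors(blank, ds)
        assert pm.unassignable[0]
        np.testing.assert_allclose(pm.q[0], [0.5, 0.5])

    def test_loo_equals_remove_and_reassign(self, small_baseline):
        dataset, _ = small_baseline
        queries = pool_collections(dataset.collections, "self")
        home = [c.id for c in dataset.collections for _ in c.individual_ids]
        pm = assignment_posteriors(queries, dataset, leave_one_out=True, home_pops=home)
        # physically remove fish 0 of population 0 and re-assign it
        c0 = dataset.collections[0]
        reduced0 = GenotypeCollection(
            id=c0.id,
            individual_ids=c0.individual_ids[1:],
            loci=c0.loci,
            calls=c0.calls[1:],
        )
        reduced = BaselineDataset(
            collections=[reduced0] + dataset.collections[1:],
            hierarchy=dataset.hierarchy,
            loci=dataset.loci,
        )
        one = GenotypeCollection(
            id="one", individual_ids=[c0.individual_ids[0]],
            loci=dataset.loci, calls=c0.calls[[0]],
        )
        direct = assignment_posteriors(one, reduced)
        np.testing.assert_allclose(direct.q[0], pm.q[0], atol=1e-12)

    def test_loo_without_home_pops_rejected(self, small_baseline):
        dataset, _ = small_baseline
        queries = pool_collections(dataset.collections, "self")
        with pytest.raises(ValueError, match="home_pops"):
            assignment_posteriors(queries, dataset, leave_one_out=True)


class TestGroupAggregation:
    def test_two_pops_one_group_sum(self):
        pm = PosteriorMatrix(
            individual_ids=["i1"], unit_ids=["p1", "p2"],
            q=np.array([[0.4, 0.6]]), n_scored=np.array([5]),
        )
        hier = BaselineHierarchy(pop_to_group={"p1": "g", "p2": "g"})
        gm = aggregate_to_groups(pm, hier)
        assert gm.unit_ids == ["g"]
        assert gm.q[0, 0] == pytest.approx(1.0)

    def test_singleton_groups_identity(self):
        q = np.array([[0.3, 0.7], [0.9, 0.1]])
        pm = PosteriorMatrix(
            individual_ids=["i1", "i2"], unit_ids=["p1", "p2"],
            q=q, n_scored=np.array([5, 5]),
        )
        hier = BaselineHierarchy(pop_to_group={"p1": "g1", "p2": "g2"})
        gm = aggregate_to_groups(pm, hier)
        np.testing.assert_allclose(gm.q, q)

    def test_row_sums_preserved_random(self):
        rng = np.random.default_rng(0)
        q = rng.dirichlet(np.ones(6), size=20)
        pm = PosteriorMatrix(
            individual_ids=[f"i{j}" for j in range(20)],
            unit_ids=[f"p{j}" for j in range(6)],
            q=q, n_scored=np.full(20, 3),
        )
        hier = BaselineHierarchy(
            pop_to_group={f"p{j}": f"g{j % 2}" for j in range(6)}
        )
        gm = aggregate_to_groups(pm, hier)
        np.testing.assert_allclose(gm.q.sum(axis=1), 1.0, atol=1e-12)


class TestSelfAssignment:
    def test_divergent_populations_high_accuracy(self):
        loci = [Locus(f"L{l}", (101, 103, 105, 107)) for l in range(6)]
        rng = np.random.default_rng(1)
        # disjoint alleles: pop a uses indices {0,1}, pop b uses {2,3}
        calls_a = rng.integers(0, 2, size=(50, 6, 2))
        calls_b = rng.integers(2, 4, size=(50, 6, 2))
        a = make_collection("a", calls_a.tolist(), loci)
        b = make_collection("b", calls_b.tolist(), loci)
        hier = BaselineHierarchy(pop_to_group={"a": "ga", "b": "gb"})
        ds = BaselineDataset(collections=[a, b], hierarchy=hier, loci=loci)
        conf = self_assignment_confusion(ds, level="population")
        assert conf.accuracy >= 0.98
        assert conf.counts.sum(axis=1).tolist() == [50, 50]

    def test_identical_populations_near_chance(self):
        spec = SyntheticBaselineSpec(
            n_groups=1, pops_per_group=2, f_between=0.0, f_within=0.0,
            n_loci=10, alleles_per_locus=8, n_per_pop=50, seed=2,
        )
        dataset, _ = generate_baseline(spec)
        conf = self_assignment_confusion(dataset, level="population")
        # binomial around 0.5 with n = 100
        assert 0.30 < conf.accuracy < 0.70

    def test_accuracy_increases_with_divergence(self):
        accs = []
        for F in (0.01, 0.05, 0.2):
            vals = []
            for seed in range(3):
                spec = SyntheticBaselineSpec(
                    n_groups=3, pops_per_group=1, f_between=F, f_within=0.0,
                    n_loci=10, alleles_per_locus=8, n_per_pop=40, seed=seed,
                )
                dataset, _ = generate_baseline(spec)
                vals.append(self_assignment_confusion(dataset).accuracy)
            accs.append(np.mean(vals))
        assert accs[0] <= accs[1] <= accs[2]


class TestMixtureEstimation:
    def test_mean_posterior_hand_value(self):
        pm = PosteriorMatrix(
            individual_ids=["i1", "i2"], unit_ids=["p1", "p2"],
            q=np.array([[1.0, 0.0], [0.5, 0.5]]), n_scored=np.array([5, 5]),
        )
        est = estimate_mixture(pm, method="mean-posterior")
        np.testing.assert_allclose(est.proportions, [0.75, 0.25])
        assert est.counts.sum() == 2

    def test_em_degenerate_equals_empirical_fractions(self):
        # fully divergent baseline: posteriors are 0/1 indicators
        q = np.array([[1.0, 0.0]] * 7 + [[0.0, 1.0]] * 3)
        pm = PosteriorMatrix(
            individual_ids=[f"i{j}" for j in range(10)], unit_ids=["p1", "p2"],
            q=q, n_scored=np.full(10, 5),
        )
        est = estimate_mixture(pm, method="em")
        np.testing.assert_allclose(est.proportions, [0.7, 0.3], atol=1e-6)
        assert est.counts.tolist() == [7, 3]

    def test_em_and_mean_posterior_agree_when_divergent(self):
        rng = np.random.default_rng(4)
        hard = rng.dirichlet(np.full(3, 0.005), size=100)  # near-degenerate rows
        pm = PosteriorMatrix(
            individual_ids=[f"i{j}" for j in range(100)],
            unit_ids=["p1", "p2", "p3"],
            q=hard, n_scored=np.full(100, 5),
        )
        mp = estimate_mixture(pm, method="mean-posterior")
        em = estimate_mixture(pm, method="em")
        assert np.max(np.abs(mp.proportions - em.proportions)) < 0.01

    def test_em_loglik_monotone_and_self_consistent(self, small_baseline):
        dataset, truth = small_baseline
        pops = dataset.pop_ids
        mix, _ = generate_mixture(
            truth, {pops[0]: 0.6, pops[3]: 0.4}, n=100, seed=21
        )
        from gsikit.io import assemble_dataset, remap_collection

        ds = assemble_dataset(
            dataset.collections, dataset.hierarchy, extra_loci=[mix.loci]
        )
        mix = remap_collection(mix, ds.loci)
        pm = assignment_posteriors(mix, ds)
        est = estimate_mixture(pm, method="em", tol=1e-10)
        assert est.converged
        # fixed point: pi = mean of posterior responsibilities under pi
        W = est.proportions[None, :] * pm.q
        W /= W.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(W.mean(axis=0), est.proportions, atol=1e-6)

    def test_group_level_requires_hierarchy(self):
        pm = PosteriorMatrix(
            individual_ids=["i"], unit_ids=["p1", "p2"],
            q=np.array([[0.5, 0.5]]), n_scored=np.array([3]),
        )
        with pytest.raises(ValueError, match="hierarchy"):
            estimate_mixture(pm, level="group")


class TestMajorContributors:
    def test_threshold_flags(self):
        pm = PosteriorMatrix(
            individual_ids=["i1", "i2"], unit_ids=["west_cascade", "other"],
            q=np.array([[0.9, 0.1], [0.52, 0.48]]), n_scored=np.array([5, 5]),
        )
        est = estimate_mixture(pm)  # proportions (0.71, 0.29)
        table = report_major_contributors(est, threshold=0.10)
        assert table.loc[table["unit"] == "west_cascade", "major"].item()
        assert set(table.columns) >= {"unit", "proportion", "count", "major"}

    def test_just_below_threshold_not_major(self):
        pm = PosteriorMatrix(
            individual_ids=["i"], unit_ids=["a", "b"],
            q=np.array([[0.09, 0.91]]), n_scored=np.array([5]),
        )
        est = estimate_mixture(pm)
        table = report_major_contributors(est, threshold=0.10)
        assert not table.loc[table["unit"] == "a", "major"].item()

    def test_threshold_zero_all_major(self):
        pm = PosteriorMatrix(
            individual_ids=["i"], unit_ids=["a", "b"],
            q=np.array([[0.2, 0.8]]), n_scored=np.array([5]),
        )
        est = estimate_mixture(pm)
        table = report_major_contributors(est, threshold=0.0)
        assert table["major"].all()
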