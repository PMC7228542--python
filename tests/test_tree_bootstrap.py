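import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rdstreeboot.io_cli import fixture_forest
from rdstreeboot.rds_simulator import ForestDesign, RecruitmentForest
from rdstreeboot.tree_bootstrap import (
    bootstrap_ci,
    bootstrap_replicates,
    bootstrap_variance,
    exact_distribution,
    per_tree_count,
    resample_origin_ids,
    tree_resample,
)
from rdstreeboot.estimators import sample_mean, vh_estimate

from conftest import random_forest


def brute_force_mean_law(forest):
    """Direct enumeration of the bootstrap-mean law over all joint outcomes.

    Enumerates every assignment of source trees to the k root slots and,
    independently, every order-distinguished resampled tree of each chosen
    source tree; aggregates the uniform law of the resulting mean.
    """
    per_seed = [
        _enumerate(forest, int(r), forest.trait.astype(float)) for r in forest.roots()
    ]
    k = forest.design.num_seeds
    law = {}
    outcomes = 0
    for roots in itertools.product(range(k), repeat=k):
        for sums in itertools.product(*(per_seed[j] for j in roots)):
            val = round(sum(sums) / forest.num_nodes, 12)
            law[val] = law.get(val, 0) + 1
            outcomes += 1
    return {v: c / outcomes for v, c in sorted(law.items())}


def _enumerate(forest, node, values):
    kids = forest.children(node)
    if kids.size == 0:
        return [values[node]]
    opts = []
    for c in kids:
        opts.extend(_enumerate(forest, int(c), values))
    return [
        values[node] + sum(combo)
        for combo in itertools.product(opts, repeat=forest.design.branching)
    ]


class TestTreeResample:
    def test_height_zero_is_iid_seed_resampling(self):
        f = fixture_forest("three_seeds_h0")
        rep = tree_resample(f, rng_seed=0)
        assert set(rep.origin) <= set(f.roots())
        np.testing.assert_array_equal(rep.forest.trait, f.trait[rep.origin])

    def test_single_chain_resample_is_identity(self):
        f = fixture_forest("chain_m1")
        for seed in range(5):
            rep = tree_resample(f, rng_seed=seed)
            np.testing.assert_array_equal(rep.origin, np.arange(f.num_nodes))
            np.testing.assert_array_equal(rep.forest.trait, f.trait)

    def test_origin_links_respect_tree_structure(self):
        f = random_forest(ForestDesign(3, 2, 2), np.random.default_rng(0))
        rep = tree_resample(f, rng_seed=1)
        roots = set(f.roots())
        for s in range(f.num_nodes):
            o = int(rep.origin[s])
            if rep.forest.parent[s] < 0:
                assert o in roots
            else:
                parent_origin = int(rep.origin[rep.forest.parent[s]])
                assert o in f.children(parent_origin)
            assert rep.forest.trait[s] == f.trait[o]
            assert rep.forest.degree[s] == f.degree[o]

    def test_replicate_preserves_design(self):
        f = fixture_forest("two_trees_h2")
        rep = tree_resample(f, rng_seed=2)
        assert rep.forest.design == f.design
        assert rep.forest.num_nodes == f.num_nodes

    def test_child_pair_resampling_frequencies(self):
        """k=1, m=2, h=1, child traits (0,1): the four ordered child picks
        give pair sums (0, 1, 2) with probabilities (1/4, 1/2, 1/4)."""
        f = RecruitmentForest(design=ForestDesign(1, 2, 1), trait=[1, 0, 1], degree=[1, 1, 1])
        B = 40_000
        summ = bootstrap_replicates(f, "mean", B, rng_seed=3)
        child_sums = np.rint(summ.replicate_values * 3 - 1).astype(int)
        freq = np.bincount(child_sums, minlength=3) / B
        for target, got in zip((0.25, 0.5, 0.25), freq):
            se = np.sqrt(target * (1 - target) / B)
            assert abs(got - target) < 3 * se


class TestExactDistribution:
    def test_single_tree_worked_example(self):
        """Exhaustive enumeration of the 4 resampled trees of the (1,0,1) tree."""
        dist = exact_distribution(fixture_forest("single_tree_h1"))
        np.testing.assert_allclose(dist.support, [1 / 3, 2 / 3, 1.0], atol=1e-12)
        np.testing.assert_allclose(dist.probability, [0.25, 0.5, 0.25], atol=1e-12)
        assert dist.per_tree_count == 4
        assert dist.total_count == 4
        assert dist.mean == pytest.approx(2 / 3, abs=1e-12)
        assert dist.variance == pytest.approx(1 / 18, abs=1e-12)

    def test_seed_only_forest_matches_multinomial_bootstrap(self):
        """h=0: per-draw support {0,1}, a=1, K=3; var of mean = (2/9)/3."""
        dist = exact_distribution(fixture_forest("three_seeds_h0"))
        assert dist.per_tree_count == 1
        assert dist.total_count == 3
        assert dist.variance == pytest.approx((2 / 9) / 3, abs=1e-12)

    @pytest.mark.parametrize("m,h", [(2, 1), (2, 2), (3, 1)])
    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_exact_mean_is_sample_mean(self, m, h, k):
        """The bootstrap mean is exactly unbiased for X_bar."""
        rng = np.random.default_rng(100 * m + 10 * h + k)
        for _ in range(3):
            f = random_forest(ForestDesign(k, m, h), rng)
            dist = exact_distribution(f)
            assert dist.probability.sum() == pytest.approx(1.0, abs=1e-12)
            assert dist.mean == pytest.approx(sample_mean(f).value, abs=1e-12)

    def test_per_tree_count_recursion(self):
        # f(0)=1, f(d) = (m f(d-1))^m
        assert per_tree_count(ForestDesign(1, 2, 1)) == 4
        assert per_tree_count(ForestDesign(1, 2, 2)) == 64
        assert per_tree_count(ForestDesign(1, 3, 1)) == 27
        assert per_tree_count(ForestDesign(1, 1, 5)) == 1

    def test_convolution_matches_joint_enumeration(self):
        """k-fold convolution of the single-draw law equals brute force over
        all joint (root assignment, resampled tree) outcomes."""
        for seed, design in [(0, ForestDesign(2, 2, 1)), (1, ForestDesign(3, 2, 1))]:
            f = random_forest(design, np.random.default_rng(seed))
            dist = exact_distribution(f)
            oracle = brute_force_mean_law(f)
            got = {round(float(v), 12): float(p) for v, p in zip(dist.support, dist.probability)}
            assert set(got) == set(oracle)
            for v, p in oracle.items():
                assert got[v] == pytest.approx(p, abs=1e-12)

    def test_enumeration_guard(self):
        f = random_forest(ForestDesign(1, 2, 4), np.random.default_rng(2))
        with pytest.raises(ValueError, match="Monte Carlo"):
            exact_distribution(f)

    def test_vh_has_no_exact_enumeration(self):
        with pytest.raises(ValueError, match="relabel"):
            exact_distribution(fixture_forest("single_tree_h1"), "vh")

    def test_ipw_enumeration_via_relabelled_values(self):
        """IPW is the sample mean of relabelled values, so its exact
        bootstrap mean equals the IPW point estimate."""
        from rdstreeboot.estimators import ipw_estimate

        f = fixture_forest("two_trees_h2")
        dist = exact_distribution(f, "ipw", total_degree=40, population_size=10)
        assert dist.mean == pytest.approx(
            ipw_estimate(f, 40, 10).value, abs=1e-12
        )


class TestReplicatesAndSummaries:
    def test_constant_traits_give_zero_variance(self):
        f = RecruitmentForest(design=ForestDesign(2, 2, 1), trait=[1] * 6, degree=[2] * 6)
        summ = bootstrap_replicates(f, "mean", 200, rng_seed=0)
        assert (summ.replicate_values == 1.0).all()
        assert bootstrap_variance(summ) == 0.0

    def test_fixed_seed_is_bit_reproducible(self):
        f = fixture_forest("two_trees_h2")
        a = bootstrap_replicates(f, "vh", 500, rng_seed=7)
        b = bootstrap_replicates(f, "vh", 500, rng_seed=7)
        np.testing.assert_array_equal(a.replicate_values, b.replicate_values)

    def test_chunked_generation_has_correct_mean(self):
        """Chunking bounds memory without biasing the replicate law."""
        f = fixture_forest("two_trees_h2")
        dist = exact_distribution(f)
        b = bootstrap_replicates(f, "mean", 20_000, rng_seed=3, chunk_size=f.num_nodes * 7)
        se = np.sqrt(dist.variance / 20_000)
        assert abs(b.replicate_values.mean() - dist.mean) < 3 * se

    def test_vectorised_engine_agrees_with_estimator_recompute(self):
        """The array fast path gives the same VH values as recomputing the
        estimator on explicitly materialised replicate forests."""
        f = fixture_forest("two_trees_h2")
        rng = np.random.default_rng(5)
        ids = resample_origin_ids(f, 50, rng)
        from rdstreeboot.tree_bootstrap import _replicate_estimates

        fast = _replicate_estimates(f, "volz_heckathorn", ids, None, None)
        for b in range(50):
            rep = RecruitmentForest(
                design=f.design, trait=f.trait[ids[b]], degree=f.degree[ids[b]]
            )
            assert vh_estimate(rep).value == pytest.approx(fast[b], abs=1e-12)

    def test_monte_carlo_variance_approaches_exact(self):
        f = fixture_forest("two_trees_h2")
        dist = exact_distribution(f)
        summ = bootstrap_replicates(f, "mean", 40_000, rng_seed=11)
        # bootstrap-of-bootstrap SE for the variance estimate
        dev = summ.replicate_values - summ.replicate_values.mean()
        se = np.sqrt(np.var(dev**2) / summ.num_replicates)
        assert abs(bootstrap_variance(summ) - dist.variance) < 3 * se

    def test_unknown_estimator_rejected(self):
        with pytest.raises(ValueError, match="unknown estimator"):
            bootstrap_replicates(fixture_forest("single_tree_h1"), "salganik", 10, rng_seed=0)


class TestVarianceAndIntervals:
    def test_variance_arithmetic(self):
        from rdstreeboot.tree_bootstrap import BootstrapSummary

        def summ(vals):
            return BootstrapSummary(
                replicate_values=np.asarray(vals, float),
                estimator_name="sample_mean",
                point_estimate=float(np.mean(vals)),
            )

        assert bootstrap_variance(summ([0, 0])) == 0.0
        assert bootstrap_variance(summ([0, 1])) == 0.25  # 1/B normalisation
        with pytest.raises(ValueError):
            bootstrap_variance(summ([1.0]))

    def test_constant_replicates_zero_width_interval(self):
        from rdstreeboot.tree_bootstrap import BootstrapSummary

        s = BootstrapSummary(
            replicate_values=np.full(100, 0.4), estimator_name="sample_mean",
            point_estimate=0.4,
        )
        for method in ("percentile", "normal"):
            ci = bootstrap_ci(s, 0.95, method).interval
            assert ci == pytest.approx((0.4, 0.4), abs=1e-12)

    def test_percentile_interval_linear_interpolation(self):
        from rdstreeboot.tree_bootstrap import BootstrapSummary

        s = BootstrapSummary(
            replicate_values=np.arange(1.0, 101.0), estimator_name="sample_mean",
            point_estimate=50.5,
        )
        lo, hi = bootstrap_ci(s, 0.9, "percentile").interval
        assert lo == pytest.approx(5.95)
        assert hi == pytest.approx(95.05)

    def test_normal_interval_half_width(self):
        from scipy import stats
        from rdstreeboot.tree_bootstrap import BootstrapSummary

        rng = np.random.default_rng(0)
        s = BootstrapSummary(
            replicate_values=rng.normal(size=500), estimator_name="sample_mean",
            point_estimate=0.0,
        )
        ci = bootstrap_ci(s, 0.95, "normal")
        half = stats.norm.ppf(0.975) * np.sqrt(ci.variance)
        assert ci.interval == pytest.approx((-half, half), abs=1e-12)

    def test_invalid_level_rejected(self):
        f = fixture_forest("single_tree_h1")
        s = bootstrap_replicates(f, "mean", 50, rng_seed=0)
        with pytest.raises(ValueError, match="level"):
            bootstrap_ci(s, 1.0)


@given(
    k=st.integers(1, 3),
    m=st.integers(1, 2),
    h=st.integers(0, 2),
    seed=st.integers(0, 1000),
)
@settings(deadline=None, max_examples=30, derandomize=True)
def test_replicates_preserve_forest_shape(k, m, h, seed):
    """Every replicate has exactly the source design (n never changes)."""
    f = random_forest(ForestDesign(k, m, h), np.random.default_rng(seed))
    rep = tree_resample(f, rng_seed=seed)
    assert rep.forest.design == f.design
    assert rep.forest.num_nodes == k * f.design.nodes_per_tree
    assert set(np.unique(rep.origin)) <= set(range(f.num_nodes))
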