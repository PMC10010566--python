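"""Tests for distances, group statistics, and the group-difference tests."""

from itertools import combinations, permutations
from math import comb

import numpy as np
import pytest

from persnet.graphcore import Barcode, WeightedNetwork, birth_death_decomposition
from persnet.inference import (
    GroupExpectedBarcodes,
    TestResult,
    auc_betti0,
    etl,
    group_statistic,
    max_gap_statistic,
    permutation_test,
    wasserstein_0d,
    wasserstein_1d,
    wilcoxon_auc_test,
)
from persnet.orderstats import EmpiricalDistribution, Uniform01, expected_barcode
from persnet.synthetic import generate_iid_network


def brute_force_wasserstein(a, b):
    """Minimal L2 matching cost over every possible bijection."""
    best = np.inf
    for perm in permutations(range(len(b))):
        cost = np.sqrt(sum((a[i] - b[j]) ** 2 for i, j in enumerate(perm)))
        best = min(best, cost)
    return best


def _toy_barcode_p3(birth_ranks=(2, 3), death_ranks=(1,)):
    # any p=3 decomposition has birth ranks {2,3} and death rank {1}
    values = np.array([0.25, 0.5, 0.75])
    return Barcode(
        births=values[np.array(birth_ranks) - 1],
        deaths=values[np.array(death_ranks) - 1],
        birth_ranks=np.array(birth_ranks),
        death_ranks=np.array(death_ranks),
    )


class TestWasserstein:
    def test_identical_zero(self):
        b = np.array([0.1, 0.3, 0.9])
        assert wasserstein_0d(b, b) == 0.0

    def test_direct_formula(self):
        assert wasserstein_0d([0.1, 0.4], [0.2, 0.6]) == pytest.approx(
            np.sqrt(0.01 + 0.04)
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="node count"):
            wasserstein_0d([0.1], [0.1, 0.2])

    def test_sorted_matching_is_optimal_3pt(self, rng):
        for _ in range(50):
            a, b = rng.uniform(0, 1, (2, 3))
            assert wasserstein_0d(a, b) == pytest.approx(brute_force_wasserstein(a, b))

    @pytest.mark.parametrize("npoints", [2, 3, 4, 5])
    def test_sorted_matching_is_optimal_upto5(self, rng, npoints):
        for _ in range(25):
            a, b = rng.uniform(0, 1, (2, npoints))
            assert wasserstein_1d(a, b) == pytest.approx(brute_force_wasserstein(a, b))


class TestEtl:
    def test_identical_zero(self):
        bar = _toy_barcode_p3()
        assert etl(Uniform01(), bar, Uniform01(), bar) == 0.0

    def test_hand_evaluated_toy(self):
        # p=3: q=3, birth ranks {2,3}, death rank {1}; quantile levels
        # 2/4, 3/4 and 1/4.  Uniform gives (0.5, 0.75 | 0.25); the empirical
        # sample {0.1, 0.2, 0.9} gives (0.2, 0.9 | 0.1).
        bar = _toy_barcode_p3()
        emp = EmpiricalDistribution([0.1, 0.2, 0.9])
        expected = (0.5 - 0.2) ** 2 + (0.75 - 0.9) ** 2 + (0.25 - 0.1) ** 2
        assert etl(Uniform01(), bar, emp, bar) == pytest.approx(expected)

    def test_matching_empirical_gives_zero(self):
        bar = _toy_barcode_p3()
        emp = EmpiricalDistribution([0.25, 0.5, 0.75])
        assert etl(Uniform01(), bar, emp, bar) == pytest.approx(0.0)

    def test_wasserstein_identity(self, make_random_network):
        # ETL equals squared 0D plus squared 1D Wasserstein on the
        # expected barcodes
        net1, net2 = make_random_network(7), make_random_network(7)
        bar1, bar2 = map(birth_death_decomposition, (net1, net2))
        e1 = expected_barcode(EmpiricalDistribution(net1.weights), bar1)
        e2 = expected_barcode(EmpiricalDistribution(net2.weights), bar2)
        loss = etl(
            EmpiricalDistribution(net1.weights), bar1,
            EmpiricalDistribution(net2.weights), bar2,
        )
        w0 = wasserstein_0d(e1.expected_births, e2.expected_births)
        w1 = wasserstein_1d(e1.expected_deaths, e2.expected_deaths)
        assert loss == pytest.approx(w0**2 + w1**2)

    def test_sqrt_variant(self):
        bar = _toy_barcode_p3()
        emp = EmpiricalDistribution([0.1, 0.2, 0.9])
        assert etl(Uniform01(), bar, emp, bar, sqrt=True) == pytest.approx(
            np.sqrt(etl(Uniform01(), bar, emp, bar))
        )

    def test_mismatched_p_rejected(self, make_random_network):
        net1, net2 = make_random_network(5), make_random_network(6)
        with pytest.raises(ValueError, match="node count"):
            etl(
                Uniform01(), birth_death_decomposition(net1),
                Uniform01(), birth_death_decomposition(net2),
            )


class TestGroupStatistics:
    def _groups(self, rng, p=6, n=4, dist_a="beta(1,1)", dist_b="beta(5,2)"):
        nets_a = [generate_iid_network(p, dist_a, rng) for _ in range(n)]
        nets_b = [generate_iid_network(p, dist_b, rng) for _ in range(n)]
        return (
            GroupExpectedBarcodes.from_networks(nets_a),
            GroupExpectedBarcodes.from_networks(nets_b),
        )

    def test_identical_groups_zero(self, rng):
        ga, _ = self._groups(rng)
        assert group_statistic(ga, ga) == 0.0
        assert max_gap_statistic(ga, ga) == 0.0

    def test_label_swap_symmetry(self, rng):
        ga, gb = self._groups(rng)
        assert group_statistic(ga, gb) == pytest.approx(group_statistic(gb, ga))
        assert max_gap_statistic(ga, gb) == pytest.approx(max_gap_statistic(gb, ga))

    def test_nonnegative(self, rng):
        ga, gb = self._groups(rng)
        assert group_statistic(ga, gb) > 0
        assert max_gap_statistic(ga, gb) > 0

    def test_max_gap_single_index(self):
        births = np.array([[0.1, 0.5, 0.8]])
        deaths = np.array([[0.2, 0.3]])
        ga = GroupExpectedBarcodes(births=births, deaths=deaths)
        shifted = births.copy()
        shifted[0, 1] += 0.2
        gb = GroupExpectedBarcodes(births=shifted, deaths=deaths)
        assert max_gap_statistic(ga, gb) == pytest.approx(0.2)

    def test_group_means_sorted(self, rng):
        ga, _ = self._groups(rng)
        assert np.all(np.diff(ga.mean_births) >= 0)
        assert np.all(np.diff(ga.mean_deaths) >= 0)

    def test_power_observed_exceeds_null_quantile(self):
        # different-distribution groups: observed statistic lands above the
        # 99th percentile of its permutation null in >= 9/10 replicates
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(1000 + rep)
            nets_a = [generate_iid_network(10, "beta(1,1)", rng) for _ in range(6)]
            nets_b = [generate_iid_network(10, "beta(5,2)", rng) for _ in range(6)]
            res = permutation_test(
                nets_a, nets_b, "etl", n_perm=1000, seed=rep, return_null=True
            )
            if res.statistic_observed > np.quantile(res.null_samples, 0.99):
                hits += 1
        assert hits >= 9


class TestAuc:
    def test_fig1_formula(self, fig1_network):
        net, w = fig1_network
        bar = birth_death_decomposition(net)
        expected = 2 * (w[5] - w[3]) + 3 * (w[6] - w[5])
        assert auc_betti0(bar.births) == pytest.approx(expected)

    def test_direct_substitution(self):
        assert auc_betti0([0.3, 0.5, 0.6]) == pytest.approx(0.7)

    def test_shift_invariance(self, rng):
        u = np.sort(rng.uniform(0, 1, 8))
        assert auc_betti0(u + 3.7) == pytest.approx(auc_betti0(u))

    def test_short_input_warns(self):
        with pytest.warns(UserWarning, match="fewer than two"):
            assert auc_betti0([0.5]) == 0.0


class TestPermutationTest:
    def test_identical_groups_high_p(self, make_random_network):
        nets = [make_random_network(5) for _ in range(3)]
        res = permutation_test(nets, list(nets), "etl", n_perm=200, seed=0)
        assert res.statistic_observed == 0.0
        assert res.p_value >= 0.5

    def test_exhaustive_oracle_convergence(self, rng):
        nets_a = [generate_iid_network(6, "beta(1,1)", rng) for _ in range(2)]
        nets_b = [generate_iid_network(6, "beta(5,2)", rng) for _ in range(2)]
        exact = permutation_test(nets_a, nets_b, "etl", exhaustive=True)
        assert exact.n_permutations == comb(4, 2)
        approx = permutation_test(nets_a, nets_b, "etl", n_perm=20_000, seed=1)
        assert approx.p_value == pytest.approx(exact.p_value, abs=0.02)

    def test_exhaustive_matches_manual_enumeration(self, rng):
        nets_a = [generate_iid_network(5, "beta(1,1)", rng) for _ in range(2)]
        nets_b = [generate_iid_network(5, "beta(1,5)", rng) for _ in range(2)]
        res = permutation_test(nets_a, nets_b, "etl", exhaustive=True)
        pool = nets_a + nets_b
        observed = group_statistic(
            GroupExpectedBarcodes.from_networks(nets_a),
            GroupExpectedBarcodes.from_networks(nets_b),
        )
        null = []
        for pick in combinations(range(4), 2):
            rest = [i for i in range(4) if i not in pick]
            null.append(
                group_statistic(
                    GroupExpectedBarcodes.from_networks([pool[i] for i in pick]),
                    GroupExpectedBarcodes.from_networks([pool[i] for i in rest]),
                )
            )
        assert res.p_value == pytest.approx(np.mean(np.array(null) >= observed))

    def test_null_calibration(self):
        # same-distribution groups: p-values spread over (0, 1)
        pvals = []
        for rep in range(8):
            rng = np.random.default_rng(300 + rep)
            nets_a = [generate_iid_network(10, "beta(1,1)", rng) for _ in range(6)]
            nets_b = [generate_iid_network(10, "beta(1,1)", rng) for _ in range(6)]
            pvals.append(
                permutation_test(nets_a, nets_b, "etl", n_perm=500, seed=rep).p_value
            )
        pvals = np.array(pvals)
        assert np.mean(pvals < 0.05) <= 0.25
        assert pvals.max() > 0.2

    def test_seed_reproducible(self, rng):
        nets_a = [generate_iid_network(6, "beta(1,1)", rng) for _ in range(3)]
        nets_b = [generate_iid_network(6, "beta(5,2)", rng) for _ in range(3)]
        r1 = permutation_test(nets_a, nets_b, "maxgap", n_perm=300, seed=9)
        r2 = permutation_test(nets_a, nets_b, "maxgap", n_perm=300, seed=9)
        assert r1.p_value == r2.p_value

    def test_label_swap_invariance(self, rng):
        # exact invariance under exhaustive enumeration; random permutation
        # p-values agree in distribution (checked approximately)
        nets_a = [generate_iid_network(6, "beta(1,1)", rng) for _ in range(3)]
        nets_b = [generate_iid_network(6, "beta(5,2)", rng) for _ in range(3)]
        r1 = permutation_test(nets_a, nets_b, "etl", exhaustive=True)
        r2 = permutation_test(nets_b, nets_a, "etl", exhaustive=True)
        assert r1.p_value == r2.p_value
        s1 = permutation_test(nets_a, nets_b, "etl", n_perm=4000, seed=5)
        s2 = permutation_test(nets_b, nets_a, "etl", n_perm=4000, seed=5)
        assert s1.p_value == pytest.approx(s2.p_value, abs=0.05)

    def test_add_one_estimator_bounds(self, rng):
        nets_a = [generate_iid_network(8, "beta(1,1)", rng) for _ in range(4)]
        nets_b = [generate_iid_network(8, "beta(1,5)", rng) for _ in range(4)]
        res = permutation_test(nets_a, nets_b, "etl", n_perm=100, seed=0)
        assert res.p_value >= 1 / 101
        assert res.p_value_plain >= 0.0

    def test_empty_group_rejected(self, make_random_network):
        with pytest.raises(ValueError, match="non-empty"):
            permutation_test([], [make_random_network(5)])

    def test_bad_statistic_rejected(self, make_random_network):
        nets = [make_random_network(5)]
        with pytest.raises(ValueError, match="statistic"):
            permutation_test(nets, nets, statistic="bogus")


def wilcoxon_enumeration_oracle(auc_a, auc_b):
    """Exact two-sided rank-sum p-value by full enumeration of assignments."""
    pooled = np.concatenate([auc_a, auc_b])
    m = len(auc_a)
    ranks = np.argsort(np.argsort(pooled)) + 1
    u_obs = ranks[:m].sum() - m * (m + 1) / 2
    null = []
    for pick in combinations(range(len(pooled)), m):
        null.append(ranks[list(pick)].sum() - m * (m + 1) / 2)
    null = np.array(null)
    p_lo = np.mean(null <= u_obs)
    p_hi = np.mean(null >= u_obs)
    return min(1.0, 2 * min(p_lo, p_hi))


class TestWilcoxonAucTest:
    def test_complete_separation_6v6(self):
        # groups whose AUCs fully separate give the minimal exact two-sided
        # p-value 2 / C(12, 6)
        rng = np.random.default_rng(12)
        nets_a = [generate_iid_network(20, "beta(5,2)", rng) for _ in range(6)]
        nets_b = [generate_iid_network(20, "beta(1,5)", rng) for _ in range(6)]
        res = wilcoxon_auc_test(nets_a, nets_b)
        auc_a, auc_b = res.extras["auc_a"], res.extras["auc_b"]
        separated = min(auc_a) > max(auc_b) or min(auc_b) > max(auc_a)
        assert separated  # sanity: complete separation
        assert res.p_value == pytest.approx(2 / comb(12, 6), rel=1e-10)

    def test_identical_groups_p_one(self, make_random_network):
        nets = [make_random_network(6) for _ in range(4)]
        res = wilcoxon_auc_test(nets, list(nets))
        assert res.p_value == pytest.approx(1.0)

    def test_enumeration_oracle_4v4(self):
        for seed in range(5):
            rng = np.random.default_rng(600 + seed)
            nets_a = [generate_iid_network(8, "beta(1,1)", rng) for _ in range(4)]
            nets_b = [generate_iid_network(8, "beta(5,2)", rng) for _ in range(4)]
            res = wilcoxon_auc_test(nets_a, nets_b)
            oracle = wilcoxon_enumeration_oracle(
                res.extras["auc_a"], res.extras["auc_b"]
            )
            assert res.p_value == pytest.approx(oracle, rel=1e-9)

    def test_rank_sum_statistic(self):
        rng = np.random.default_rng(77)
        nets_a = [generate_iid_network(8, "beta(1,1)", rng) for _ in range(4)]
        nets_b = [generate_iid_network(8, "beta(1,1)", rng) for _ in range(4)]
        res = wilcoxon_auc_test(nets_a, nets_b)
        pooled = np.concatenate([res.extras["auc_a"], res.extras["auc_b"]])
        ranks = np.argsort(np.argsort(pooled)) + 1
        assert res.statistic_observed == pytest.approx(ranks[:4].sum())


class TestTestResult:
    def test_p_value_validated(self):
        with pytest.raises(ValueError, match="p-value"):
            TestResult(0.0, 1.5, 10, 0, "x")
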