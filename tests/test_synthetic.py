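"""Generators: determinism, known moments, and ground-truth invariants."""

import math

import numpy as np
import pytest

import volvoclock as vc
from volvoclock.rate_models import RateProcessParams


class TestBirthDeathTree:
    def test_two_tips_single_split(self):
        t = vc.sim_bd_tree(2, 0.5, 0.0, seed=0)
        assert t.n_tips == 2
        assert t.n_nodes == 3

    @pytest.mark.parametrize("n", [5, 20])
    def test_tip_and_internal_counts(self, n):
        t = vc.sim_bd_tree(n, 0.1, 0.03, seed=1)
        assert t.n_tips == n
        assert t.n_nodes == 2 * n - 1  # n-1 internal nodes
        assert t.is_binary()

    def test_ages_strictly_ordered(self):
        t = vc.sim_bd_tree(15, 0.1, 0.05, seed=2)
        for v in range(t.n_nodes):
            if t.parent[v] >= 0:
                assert t.ages[t.parent[v]] > t.ages[v]

    def test_yule_mean_root_age(self):
        """Pure birth: E[root age] = sum_{k=2}^{n} 1/(k lambda)."""
        lam, n, reps = 0.3, 6, 1000
        ages = [vc.sim_bd_tree(n, lam, 0.0, seed=s).ages.max() for s in range(reps)]
        expected = sum(1.0 / (k * lam) for k in range(2, n + 1))
        se = np.std(ages) / math.sqrt(reps)
        assert abs(np.mean(ages) - expected) < 3 * se

    def test_seed_determinism(self):
        a = vc.sim_bd_tree(12, 0.1, 0.04, seed=9)
        b = vc.sim_bd_tree(12, 0.1, 0.04, seed=9)
        assert a.parent == b.parent and np.array_equal(a.ages, b.ages)

    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            vc.sim_bd_tree(5, 0.1, 0.2, seed=0)


class TestRates:
    def test_zero_variance_strict_clock(self):
        t = vc.sim_bd_tree(10, 0.1, 0.0, seed=3)
        for model in ("LN", "UGAM", "WN"):
            params = RateProcessParams(model, 1e-3, 0.0)
            r = vc.sim_rates(t, params, seed=0)
            nonroot = [v for v in range(t.n_nodes) if t.parent[v] >= 0]
            assert np.allclose(r[nonroot], 1e-3)

    def test_ugam_moments(self):
        t = vc.sim_bd_tree(400, 0.1, 0.0, seed=4)
        nu, s2 = 1e-3, 2.5e-7
        draws = []
        for seed in range(15):
            r = vc.sim_rates(t, RateProcessParams("UGAM", nu, s2), seed=seed)
            draws.extend(r[v] for v in range(t.n_nodes) if t.parent[v] >= 0)
        draws = np.array(draws)
        n = len(draws)
        assert abs(draws.mean() - nu) < 3 * math.sqrt(s2 / n)
        assert abs(draws.var() - s2) < 0.15 * s2

    def test_ln_parent_child_correlation_positive(self):
        t = vc.sim_bd_tree(200, 0.05, 0.0, seed=5)
        params = RateProcessParams("LN", 1e-3, 1e-3)
        pairs = []
        for seed in range(10):
            r = vc.sim_rates(t, params, seed=seed)
            for v in range(t.n_nodes):
                p = t.parent[v]
                if p >= 0 and t.parent[p] >= 0:
                    pairs.append((math.log(r[p]), math.log(r[v])))
        pairs = np.array(pairs)
        corr = np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1]
        assert corr > 0.3

    def test_cir_stationarity_enforced(self):
        t = vc.sim_bd_tree(5, 0.1, 0.0, seed=6)
        bad = RateProcessParams("CIR", 1e-3, 1.0, reversion=0.01)
        with pytest.raises(ValueError, match="stationarity"):
            vc.sim_rates(t, bad, seed=0)


class TestBranchData:
    def test_poisson_mean_formula(self):
        t = vc.sim_bd_tree(10, 0.1, 0.0, seed=7)
        rates = np.full(t.n_nodes, 1e-3)
        durations = t.durations()
        reps = [vc.sim_branch_data(t, rates, 1000, seed=s).counts for s in range(300)]
        mean_counts = np.mean(reps, axis=0)
        expected = rates * durations * 1000
        nonroot = [v for v in range(t.n_nodes) if t.parent[v] >= 0]
        for v in nonroot:
            se = math.sqrt(expected[v] / 300) if expected[v] > 0 else 1.0
            assert abs(mean_counts[v] - expected[v]) < 4 * se

    def test_unbiased_length_estimator(self):
        t = vc.sim_bd_tree(10, 0.1, 0.0, seed=8)
        rates = np.full(t.n_nodes, 2e-3)
        durations = t.durations()
        reps = 400
        sites = 500
        lengths = np.mean(
            [vc.sim_branch_data(t, rates, sites, seed=s).lengths
             for s in range(reps)],
            axis=0,
        )
        nonroot = [v for v in range(t.n_nodes) if t.parent[v] >= 0]
        true_len = rates * durations
        for v in nonroot:
            # SE of the mean estimated length: sqrt(lambda)/(sites*sqrt(reps))
            se = math.sqrt(true_len[v] * sites) / (sites * math.sqrt(reps))
            assert abs(lengths[v] - true_len[v]) < 4 * se + 1e-12


class TestTraits:
    def test_zero_rate_all_tips_root_state(self):
        t = vc.sim_bd_tree(10, 0.1, 0.0, seed=9)
        model = vc.MkModel(["a", "b"], "ER", [0.0])
        tips, truth = vc.sim_traits(t, model, "a", seed=0)
        assert set(tips.values()) == {"a"}
        assert all(len(segs) == 1 for segs in truth.histories[0].values())

    def test_long_branch_stationary_frequencies(self):
        """On a very long branch the tip state distribution approaches the
        stationary law of the rate matrix."""
        from volvoclock.tree import build_tree

        tree = build_tree(
            [(0, 1), (0, 2)], {1: "A", 2: "B"},
            lengths={1: 500.0, 2: 500.0}, length_kind="my",
        )
        model = vc.MkModel(["a", "b"], "ARD", [0.03, 0.01])
        pi = model.stationary_distribution()
        n = 2000
        hits = sum(
            vc.sim_traits(tree, model, "a", seed=s)[0]["A"] == "a"
            for s in range(n)
        )
        se = math.sqrt(pi[0] * (1 - pi[0]) / n)
        assert abs(hits / n - pi[0]) < 3 * se

    def test_true_history_bounded_by_fitch(self):
        for seed in range(20):
            t = vc.sim_bd_tree(12, 0.1, 0.0, seed=seed)
            model = vc.MkModel(["0", "1"], "ER", [0.02])
            tips, truth = vc.sim_traits(t, model, "0", seed=seed)
            if len(set(tips.values())) < 2:
                continue
            fitch, _ = vc.fitch_count(t, tips, states=["0", "1"])
            true_changes = sum(
                len(segs) - 1 for segs in truth.histories[0].values()
            )
            assert true_changes >= fitch


class TestCalibrations:
    def test_truth_always_inside_bounds(self):
        t = vc.sim_bd_tree(15, 0.05, 0.01, seed=10)
        internal = [v for v in range(t.n_nodes) if not t.is_tip(v)]
        cals = vc.sim_calibrations(t, internal[:5], width=10.0, seed=1)
        resolved = vc.resolve_calibrations(t, cals)
        for node, cal in resolved.items():
            assert cal.min_age <= t.ages[node] <= cal.max_age

    def test_zero_width_degenerate(self):
        t = vc.sim_bd_tree(8, 0.05, 0.0, seed=11)
        cals = vc.sim_calibrations(t, [t.root], width=0.0, seed=0)
        assert cals[0].max_age - cals[0].min_age < 1e-5

    def test_planted_outlier_shifts_one_row(self):
        t = vc.sim_bd_tree(15, 0.05, 0.01, seed=12)
        internal = [v for v in range(t.n_nodes) if not t.is_tip(v)]
        nodes = internal[:3]
        clean = vc.sim_calibrations(t, nodes, width=5.0, seed=2)
        planted = vc.sim_calibrations(
            t, nodes, width=5.0, seed=2,
            outlier_node=nodes[1], outlier_offset=500.0,
        )
        assert planted[1].min_age == pytest.approx(clean[1].min_age + 500.0)
        assert planted[0].min_age == pytest.approx(clean[0].min_age)


class TestSeqPair:
    def test_target_100_identical(self):
        a, b = vc.sim_seq_pair(50, 100.0, seed=0)
        assert a == b

    def test_target_75_length_4(self):
        a, b = vc.sim_seq_pair(4, 75.0, seed=1)
        assert sum(x == y for x, y in zip(a, b)) == 3

    @pytest.mark.parametrize("seed", range(5))
    def test_measured_identity_within_resolution(self, seed):
        L, target = 200, 92.5
        a, b = vc.sim_seq_pair(L, target, seed=seed)
        measured = 100.0 * sum(x == y for x, y in zip(a, b)) / L
        assert abs(measured - target) <= 100.0 / L
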