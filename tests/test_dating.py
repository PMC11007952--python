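"""Dating MCMC: observation model, sampler correctness, summaries, x-val."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import volvoclock as vc
from volvoclock.dating import DatingModel, _Sampler, mcmc_date, fossil_cross_validate
from volvoclock.posterior import (
    convergence_check,
    format_hpd,
    hpd_interval,
    summarize_chronogram,
)
from volvoclock.rate_models import RateProcessParams
from volvoclock.synthetic import BranchData
from volvoclock.tables import Calibration, CalibrationTable


def make_problem(seed, model_name="UGAM", n_tips=10, sites=1000, n_cal=3,
                 width_frac=0.1):
    params = {
        "UGAM": RateProcessParams("UGAM", 1e-3, 2.5e-7),
        "WN": RateProcessParams("WN", 1e-3, 1.25e-5),
        "LN": RateProcessParams("LN", 1e-3, 5e-4),
        "CIR": RateProcessParams("CIR", 1e-3, 2e-5, 0.05),
    }[model_name]
    tree = vc.sim_bd_tree(n_tips, 0.02, 0.01, seed=seed)
    rates = vc.sim_rates(tree, params, seed=seed + 1000)
    data = vc.sim_branch_data(tree, rates, sites, seed=seed + 2000)
    internal = [
        v for v in range(tree.n_nodes) if not tree.is_tip(v) and v != tree.root
    ]
    rng = np.random.default_rng(seed + 3000)
    nodes = [tree.root] + list(
        rng.choice(internal, min(n_cal - 1, len(internal)), replace=False)
    )
    cals = vc.sim_calibrations(
        tree, nodes, width=width_frac * float(tree.ages[tree.root]),
        seed=seed + 4000,
    )
    model = DatingModel(
        tree=tree, calibrations=cals, clock=params,
        root_max=2 * float(tree.ages.max()),
    )
    return tree, rates, data, model


class TestBranchLoglik:
    def test_poisson_mean_arithmetic(self, two_tip_tree):
        """rate 0.001/My x 100 My x 1000 sites -> Poisson mean 100."""
        from volvoclock.tree import build_tree

        tree = build_tree(
            [(0, 1), (0, 2)], {1: "A", 2: "B"},
            lengths={1: 100.0, 2: 100.0}, length_kind="my",
        )
        counts = np.array([0, 100, 100])
        data = BranchData(lengths=counts / 1000, mode="poisson",
                         counts=counts, sites=1000)
        rates = np.array([0.0, 1e-3, 1e-3])
        ll = vc.branch_loglik(tree, rates, data)
        lam = 1e-3 * 100.0 * 1000
        expected = 2 * (100 * math.log(lam) - lam - math.lgamma(101))
        assert ll == pytest.approx(expected, abs=1e-9)

    def test_poisson_profile_mle(self):
        """rate x duration = count/sites is the exact stationary point of
        the per-branch Poisson log-likelihood."""
        from volvoclock.tree import build_tree

        tree = build_tree(
            [(0, 1), (0, 2)], {1: "A", 2: "B"},
            lengths={1: 50.0, 2: 50.0}, length_kind="my",
        )
        counts = np.array([0, 73, 41])
        data = BranchData(lengths=counts / 500, mode="poisson",
                         counts=counts, sites=500)
        rate_star = 73 / 500 / 50.0  # analytic MLE for the first branch

        def ll(rate):
            return vc.branch_loglik(tree, np.array([0.0, rate, 1e-3]), data)

        # the score (d loglik / d rate = c/rate - dur*sites) vanishes there
        score = 73 / rate_star - 50.0 * 500
        assert score == pytest.approx(0.0, abs=1e-12 * 50 * 500)
        # and the likelihood is locally maximal at the analytic optimum
        assert ll(rate_star) > ll(rate_star * (1 + 1e-4))
        assert ll(rate_star) > ll(rate_star * (1 - 1e-4))

    def test_normal_se_to_zero_pins_length(self):
        from volvoclock.tree import build_tree

        tree = build_tree(
            [(0, 1), (0, 2)], {1: "A", 2: "B"},
            lengths={1: 10.0, 2: 10.0}, length_kind="my",
        )
        obs = np.array([0.0, 0.02, 0.02])
        data = BranchData(lengths=obs, mode="normal",
                         ses=np.full(3, 1e-9), sites=None)
        good = vc.branch_loglik(tree, np.array([0.0, 0.002, 0.002]), data)
        off = vc.branch_loglik(tree, np.array([0.0, 0.0021, 0.002]), data)
        assert good > off + 1e6

    def test_zero_duration_nonzero_count_raises(self):
        from volvoclock.tree import build_tree

        tree = build_tree(
            [(0, 1), (0, 2)], {1: "A", 2: "B"},
            lengths={1: 0.0, 2: 1.0}, length_kind="my",
        )
        counts = np.array([0, 5, 5])
        data = BranchData(lengths=counts / 100, mode="poisson",
                         counts=counts, sites=100)
        with pytest.raises(ValueError, match="zero-duration"):
            vc.branch_loglik(tree, np.array([0.0, 1e-3, 1e-3]), data)


class TestSamplerCorrectness:
    @pytest.mark.parametrize("model_name", ["UGAM", "WN", "LN", "CIR"])
    def test_cached_posterior_equals_full_recompute(self, model_name):
        """After hundreds of incremental moves the cached posterior terms
        agree exactly with a from-scratch recomputation."""
        tree, rates, data, model = make_problem(5, model_name)
        sampler = _Sampler(model, data, np.random.default_rng(0))
        for i in range(40):
            sampler.sweep(i)
        cached = sampler.log_posterior()
        assert cached == pytest.approx(sampler.full_log_posterior(), abs=1e-8)

    def test_identical_seeds_identical_streams(self):
        tree, rates, data, model = make_problem(6)
        s1 = mcmc_date(model, data, n_gen=200, sample_every=5, seed=3, n_chains=2)
        s2 = mcmc_date(model, data, n_gen=200, sample_every=5, seed=3, n_chains=2)
        assert np.array_equal(s1.node_ages, s2.node_ages)
        assert np.array_equal(s1.rates, s2.rates)
        s3 = mcmc_date(model, data, n_gen=200, sample_every=5, seed=4, n_chains=2)
        assert not np.array_equal(s1.node_ages, s3.node_ages)

    def test_strict_clock_fully_constrained(self):
        """Strict-clock data with a tight calibration at every internal
        node: posterior mean ages land within 1% of truth."""
        params = RateProcessParams("UGAM", 1e-3, 2.5e-7)
        tree = vc.sim_bd_tree(10, 0.02, 0.01, seed=21)
        rates = vc.sim_rates(tree, RateProcessParams("UGAM", 1e-3, 0.0), seed=0)
        data = vc.sim_branch_data(tree, rates, 5000, seed=1)
        internal = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
        cals = vc.sim_calibrations(tree, internal, width=0.0, seed=2)
        model = DatingModel(
            tree=tree, calibrations=cals, clock=params,
            root_max=2 * float(tree.ages.max()),
        )
        s = mcmc_date(model, data, n_gen=1500, sample_every=3, seed=7, n_chains=1)
        for v in internal:
            post_mean = s.node_ages[:, v].mean()
            assert abs(post_mean - tree.ages[v]) / tree.ages[v] < 0.01

    def test_infeasible_start_raises(self):
        # hard-bound calibrations that contradict each other: child's hard
        # window lies entirely above the parent's
        tree = vc.read_newick("((A:1,B:1):1,C:2);", length_kind="my")
        cal_root = Calibration("root", "A", "C", 10.0, 11.0,
                               tail_low=0.0, tail_high=0.0)
        cal_in = Calibration("inner", "A", "B", 50.0, 60.0,
                             tail_low=0.0, tail_high=0.0)
        model = DatingModel(
            tree=tree, calibrations=CalibrationTable([cal_root, cal_in]),
            clock=RateProcessParams("UGAM", 1e-3, 2.5e-7), root_max=2000.0,
        )
        with pytest.raises(RuntimeError, match="feasible"):
            _Sampler(model, None, np.random.default_rng(0), prior_only=True)


class TestHpd:
    def test_uniform_interval_length(self):
        rng = np.random.default_rng(0)
        lo, hi = hpd_interval(rng.random(100_000), 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.02)

    def test_normal_quantiles(self):
        rng = np.random.default_rng(1)
        lo, hi = hpd_interval(rng.normal(size=100_000), 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_too_few_draws(self):
        with pytest.raises(ValueError, match="100"):
            hpd_interval(np.arange(50))

    @given(st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_shortest_interval_property(self, seed):
        """No contiguous window holding the same number of sorted draws is
        shorter than the reported interval."""
        rng = np.random.default_rng(seed)
        x = np.sort(rng.gamma(2.0, 1.0, 300))
        lo, hi = hpd_interval(x, 0.9)
        m = math.ceil(0.9 * len(x))
        width = hi - lo
        for i in range(len(x) - m + 1):
            assert x[i + m - 1] - x[i] >= width - 1e-12


class TestConvergence:
    def test_identical_chains_rhat_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=400)
        rep = convergence_check([{"p": x}, {"p": x.copy()}])
        row = rep.table.iloc[0]
        assert row["rhat"] == pytest.approx(1.0, abs=0.01)

    def test_iid_chains_pass(self):
        rng = np.random.default_rng(1)
        chains = [{"p": rng.normal(size=10_000)} for _ in range(2)]
        assert convergence_check(chains).passed

    def test_separated_chains_fail(self):
        rng = np.random.default_rng(2)
        chains = [
            {"p": rng.normal(0.0, 1.0, 5000)},
            {"p": rng.normal(10.0, 1.0, 5000)},
        ]
        assert not convergence_check(chains).passed

    def test_unequal_parameterization_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="unequal"):
            convergence_check(
                [{"p": rng.normal(size=100)}, {"q": rng.normal(size=100)}]
            )


class TestSummaries:
    def test_constant_draws_degenerate_interval(self, two_tip_tree):
        from volvoclock.dating import PosteriorSamples

        n = 200
        ages = np.zeros((n, 3))
        ages[:, 0] = 298.0
        samples = PosteriorSamples(
            tree=two_tip_tree, node_ages=ages, rates=np.zeros((n, 3)),
            hyper={}, chain_id=np.zeros(n, dtype=int),
            generation=np.arange(n), burnin_fraction=0.2,
        )
        chron, text = summarize_chronogram(samples)
        assert chron.mean[0] == 298.0
        assert chron.hpd_low[0] == chron.hpd_high[0] == 298.0
        assert "age=298" in text

    def test_interval_printed_older_first(self):
        assert format_hpd(237.0, 349.0) == "349-237"

    def test_mean_within_hpd(self):
        tree, rates, data, model = make_problem(8)
        s = mcmc_date(model, data, n_gen=1000, sample_every=4, seed=0, n_chains=1)
        chron, _ = summarize_chronogram(s)
        for v in range(tree.n_nodes):
            if not tree.is_tip(v):
                assert chron.hpd_low[v] <= chron.mean[v] <= chron.hpd_high[v]


class TestFossilCrossValidation:
    def test_one_row_per_calibration(self):
        tree, rates, data, model = make_problem(9, n_cal=3)
        table, ss = fossil_cross_validate(
            model, data, n_gen=300, sample_every=5, seed=0
        )
        assert len(table) == len(model.calibrations)
        assert ss == pytest.approx(table["squared_deviation"].sum())

    def test_planted_outlier_has_largest_deviation(self):
        """A calibration shifted +500 My off truth shows the largest
        absolute deviation when the others date its node."""
        seed = 31
        params = RateProcessParams("UGAM", 1e-3, 2.5e-7)
        tree = vc.sim_bd_tree(12, 0.02, 0.01, seed=seed)
        rates = vc.sim_rates(tree, params, seed=seed + 1)
        data = vc.sim_branch_data(tree, rates, 2000, seed=seed + 2)
        internal = [
            v for v in range(tree.n_nodes)
            if not tree.is_tip(v) and v != tree.root
        ]
        internal.sort(key=lambda v: -tree.ages[v])
        nodes = [tree.root, internal[0], internal[1]]
        cals = vc.sim_calibrations(
            tree, nodes, width=0.05 * float(tree.ages[tree.root]),
            seed=seed + 3, outlier_node=internal[1], outlier_offset=500.0,
        )
        model = DatingModel(
            tree=tree, calibrations=cals, clock=params,
            root_max=1000.0 + 4 * float(tree.ages.max()),
        )
        table, _ = fossil_cross_validate(
            model, data, n_gen=800, sample_every=4, seed=1
        )
        worst = table.loc[table["deviation"].abs().idxmax(), "calibration"]
        assert worst == "cal_3"  # the planted outlier is the third row

    def test_self_consistent_calibrations_small_deviations(self):
        tree, rates, data, model = make_problem(10, n_cal=3, width_frac=0.05)
        table, _ = fossil_cross_validate(
            model, data, n_gen=600, sample_every=4, seed=2
        )
        for _, row in table.iterrows():
            assert abs(row["deviation"]) < 0.5 * row["reference_age"] + 10.0

    def test_needs_two_calibrations(self):
        tree, rates, data, model = make_problem(11, n_cal=3)
        single = DatingModel(
            tree=model.tree,
            calibrations=CalibrationTable([model.calibrations[0]]),
            clock=model.clock, root_max=model.root_max,
        )
        with pytest.raises(ValueError, match="at least 2"):
            fossil_cross_validate(single, data)
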