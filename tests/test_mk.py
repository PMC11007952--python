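"""Mk likelihood, model fitting, Akaike weights, marginal reconstruction."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import volvoclock as vc
from volvoclock.mk import transition_matrices
from conftest import random_tip_states


def enumeration_loglik(tree, tips, model):
    """Brute-force sum over all internal-node state assignments."""
    k = model.k
    Q = model.rate_matrix()
    P = transition_matrices(Q, tree.durations())
    prior = model.stationary_distribution() if model.root_prior == "stationary" \
        else np.full(k, 1.0 / k)
    sidx = {s: i for i, s in enumerate(model.states)}
    internal = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internal)):
        amap = dict(zip(internal, assign))
        for t in tree.tips:
            amap[t] = sidx[tips[tree.labels[t]]]
        p = prior[amap[tree.root]]
        for v in range(tree.n_nodes):
            if tree.parent[v] >= 0:
                p *= P[v][amap[tree.parent[v]], amap[v]]
        total += p
    return math.log(total)


class TestLoglik:
    def test_two_state_closed_form(self, two_tip_tree):
        """Two tips in state 0 under ER rate q: likelihood is
        (P00^2 + P10^2)/2 with P00(t) = (1 + exp(-2qt))/2."""
        q, t = 0.3, 1.0
        model = vc.MkModel(["0", "1"], "ER", [q], root_prior="uniform")
        ll = vc.mk_loglik(two_tip_tree, {"A": "0", "B": "0"}, model)
        P00 = 0.5 * (1 + math.exp(-2 * q * t))
        P10 = 0.5 * (1 - math.exp(-2 * q * t))
        assert ll == pytest.approx(math.log(0.5 * (P00**2 + P10**2)), abs=1e-12)

    def test_rate_to_zero_limit(self, balanced_four_tip):
        """q -> 0 with identical tips: log-likelihood -> log(root prior)."""
        model = vc.MkModel(["0", "1"], "ER", [1e-12], root_prior="uniform")
        tips = {l: "0" for l in balanced_four_tip.tip_labels}
        ll = vc.mk_loglik(balanced_four_tip, tips, model)
        assert ll == pytest.approx(math.log(0.5), abs=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        tree = vc.sim_bd_tree(5, 0.3, 0.1, seed=seed)
        states = ["a", "b", "c"]
        model = vc.MkModel(
            states, "ARD", rng.uniform(0.05, 0.4, 6), root_prior="stationary"
        )
        tips = random_tip_states(tree, states, rng)
        ll = vc.mk_loglik(tree, tips, model)
        assert ll == pytest.approx(enumeration_loglik(tree, tips, model), abs=1e-8)

    def test_likelihood_sums_to_one_over_tip_assignments(self):
        """Summing the tip-data likelihood over every possible tip-state
        assignment gives exactly 1 (the CTMC is a proper distribution)."""
        tree = vc.sim_bd_tree(4, 0.3, 0.0, seed=9)
        states = ["0", "1"]
        model = vc.MkModel(states, "ER", [0.21], root_prior="stationary")
        total = 0.0
        for assign in itertools.product(states, repeat=4):
            tips = dict(zip(tree.tip_labels, assign))
            total += math.exp(vc.mk_loglik(tree, tips, model))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_unknown_symbol_raises(self, two_tip_tree):
        model = vc.MkModel(["0", "1"], "ER", [0.1])
        with pytest.raises(ValueError, match="state"):
            vc.mk_loglik(two_tip_tree, {"A": "2", "B": "0"}, model)


class TestRateMatrix:
    def test_rows_sum_to_zero(self):
        m = vc.MkModel(["a", "b", "c"], "ORDERED", [0.1, 0.2, 0.3, 0.4])
        Q = m.rate_matrix()
        assert np.allclose(Q.sum(axis=1), 0.0)
        assert Q[0, 2] == 0.0 and Q[2, 0] == 0.0  # non-adjacent forbidden

    def test_custom_mask(self):
        mask = np.array([[False, True], [False, False]])
        m = vc.MkModel(["0", "1"], "CUSTOM", [0.5], mask=mask)
        Q = m.rate_matrix()
        assert Q[0, 1] == 0.5 and Q[1, 0] == 0.0

    def test_stationary_distribution_sums_to_one(self):
        rng = np.random.default_rng(0)
        m = vc.MkModel(["a", "b", "c"], "ARD", rng.uniform(0.1, 1.0, 6))
        pi = m.stationary_distribution()
        assert pi.sum() == pytest.approx(1.0)
        assert np.allclose(pi @ m.rate_matrix(), 0.0, atol=1e-12)


class TestFit:
    def test_er_recovery_within_factor_two(self):
        """ER rate q=0.01 on 200-tip trees: fitted q within 2x of truth in
        at least 90% of 50 replicates (parameter-recovery suite)."""
        q_true = 0.01
        ok = 0
        for seed in range(50):
            tree = vc.sim_bd_tree(200, 0.05, 0.0, seed=seed)
            model = vc.MkModel(["0", "1"], "ER", [q_true])
            tips, _ = vc.sim_traits(tree, model, "0", seed=seed + 500)
            if len(set(tips.values())) < 2:
                continue
            fit = vc.fit_mk(tree, tips, "ER", states=["0", "1"], seed=seed,
                            n_restarts=2)
            q_hat = fit.model.rates[0]
            ok += q_true / 2 <= q_hat <= q_true * 2
        assert ok >= 45

    def test_er_nested_in_ard(self):
        rng = np.random.default_rng(3)
        tree = vc.sim_bd_tree(30, 0.05, 0.0, seed=3)
        model = vc.MkModel(["0", "1"], "ARD", [0.015, 0.004])
        tips, _ = vc.sim_traits(tree, model, "0", seed=77)
        fit_er = vc.fit_mk(tree, tips, "ER", states=["0", "1"], seed=0)
        fit_ard = vc.fit_mk(tree, tips, "ARD", states=["0", "1"], seed=0)
        assert fit_ard.loglik >= fit_er.loglik - 1e-6

    def test_degenerate_single_state_flagged(self, balanced_four_tip):
        tips = {l: "0" for l in balanced_four_tip.tip_labels}
        fit = vc.fit_mk(balanced_four_tip, tips, "ER", states=["0", "1"])
        assert fit.degenerate

    def test_fixture_cellularity_finite_positive(self, volvocine):
        fit = vc.fit_mk(
            volvocine.tree, volvocine.traits.column("cellularity"), "ER",
            states=["uni", "multi"], seed=0,
        )
        assert math.isfinite(fit.loglik)
        assert fit.model.rates[0] > 0
        assert not fit.degenerate


class TestAkaikeWeights:
    def test_symmetry(self):
        w = vc.akaike_weights([(-10.0, 2), (-10.0, 2)])
        assert np.allclose(w, [0.5, 0.5])

    def test_closed_form_delta_two(self):
        # AICs 10 and 12: weights 1/(1+e^-1), e^-1/(1+e^-1)
        w = vc.akaike_weights([(-3.0, 2), (-4.0, 2)])
        assert w[0] == pytest.approx(1 / (1 + math.exp(-1)), abs=1e-9)
        assert w[1] == pytest.approx(math.exp(-1) / (1 + math.exp(-1)), abs=1e-9)

    def test_dominated_model_negligible(self):
        w = vc.akaike_weights([(0.0, 1), (-25.0, 1), (-1.0, 1)])
        assert w[1] < 1e-10

    @given(st.floats(-50, 50))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_constant_shift(self, c):
        base = [(-12.3, 1), (-10.1, 3), (-15.0, 2)]
        shifted = [(ll + c, k) for ll, k in base]
        assert np.allclose(
            vc.akaike_weights(base), vc.akaike_weights(shifted), atol=1e-12
        )
        assert vc.akaike_weights(base).sum() == pytest.approx(1.0)


class TestMarginalASR:
    def test_symmetric_case_half_half(self, balanced_four_tip):
        """2 tips state 0, 2 tips state 1, equal durations, ER: the root
        marginal is exactly (1/2, 1/2) by symmetry."""
        model = vc.MkModel(["0", "1"], "ER", [0.3], root_prior="uniform")
        res = vc.marginal_asr(
            balanced_four_tip, {"A": "0", "B": "0", "C": "1", "D": "1"}, model
        )
        assert res.probabilities[balanced_four_tip.root] == pytest.approx(
            [0.5, 0.5], abs=1e-12
        )

    def test_zero_rate_limit_clean_data(self):
        tree = vc.sim_bd_tree(6, 0.3, 0.0, seed=4)
        model = vc.MkModel(["0", "1"], "ER", [1e-10], root_prior="uniform")
        tips = {l: "0" for l in tree.tip_labels}
        res = vc.marginal_asr(tree, tips, model)
        for v, p in res.probabilities.items():
            assert p[0] == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_posterior(self, seed):
        rng = np.random.default_rng(seed + 40)
        tree = vc.sim_bd_tree(5, 0.3, 0.1, seed=seed + 40)
        states = ["a", "b", "c"]
        model = vc.MkModel(
            states, "ARD", rng.uniform(0.05, 0.4, 6), root_prior="stationary"
        )
        tips = random_tip_states(tree, states, rng)
        res = vc.marginal_asr(tree, tips, model)
        # enumeration posterior at every internal node
        k = 3
        Q = model.rate_matrix()
        P = transition_matrices(Q, tree.durations())
        pi = model.stationary_distribution()
        sidx = {s: i for i, s in enumerate(states)}
        internal = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
        post = {v: np.zeros(k) for v in internal}
        for assign in itertools.product(range(k), repeat=len(internal)):
            amap = dict(zip(internal, assign))
            for t in tree.tips:
                amap[t] = sidx[tips[tree.labels[t]]]
            p = pi[amap[tree.root]]
            for v in range(tree.n_nodes):
                if tree.parent[v] >= 0:
                    p *= P[v][amap[tree.parent[v]], amap[v]]
            for v in internal:
                post[v][amap[v]] += p
        for v in internal:
            expected = post[v] / post[v].sum()
            assert res.probabilities[v] == pytest.approx(expected, abs=1e-8)

    def test_probabilities_sum_to_one(self, volvocine):
        fit = vc.fit_mk(
            volvocine.tree, volvocine.traits.column("gametes2"), "ER",
            states=["iso", "aniso"], seed=0,
        )
        res = vc.marginal_asr(
            volvocine.tree, volvocine.traits.column("gametes2"), fit.model
        )
        for p in res.probabilities.values():
            assert p.sum() == pytest.approx(1.0, abs=1e-9)
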